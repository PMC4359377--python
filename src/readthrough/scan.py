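"""Transcriptome scanning for PTS1-bearing readthrough extensions.

Each transcript contributes its annotated CDS (including the stop codon)
plus up to 300 nt of downstream sequence.  After filtering malformed or
ambiguous records and collapsing transcripts with identical 3' termini, a
readthrough extension is the in-frame peptide from just after the stop up
to (but excluding) the next in-frame stop within the downstream window.
The recoded stop itself is written as 'X', since the amino acid inserted
by the suppressing tRNA is not modelled.

Candidates are ranked by the product of RTP+ (the readthrough-propensity
score min-max scaled to [0, 1] across the scanned set, to avoid negative
products) and the PTS1 posterior of the extended C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .context import STOP_CODONS, StopCodonContext
from .pts1 import WINDOW, RLSCModel, posterior
from .ridge import RidgeModel, rtp_score

MAX_DOWNSTREAM = 300
MIN_PROTEIN_AA = 15

_ACGT = set("ACGT")


@dataclass
class TranscriptRecord:
    """A CDS (with its stop) plus downstream sequence, both sense strand."""

    id: str
    cds: str
    downstream: str

    def __post_init__(self) -> None:
        self.cds = self.cds.upper().replace("U", "T")
        self.downstream = self.downstream.upper().replace("U", "T")


@dataclass
class ExtensionCandidate:
    id: str
    scc: StopCodonContext
    extension_nt: str | None  # None: no in-frame stop within the window
    extension_aa: str | None
    cterm: str | None  # PTS1 scoring window (protein tail + extension)
    rtp: dict[str, float] = field(default_factory=dict)
    rtp_plus: float = 0.0
    pts1_posterior: float = 0.0
    product_score: float = 0.0
    rank: int = 0
    aggregated_ids: tuple[str, ...] = ()


def filter_transcripts(
    records: list[TranscriptRecord],
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Drop malformed records; total (never raises on record content).

    Removal reasons: ``frame`` (CDS length not a codon multiple), ``stop``
    (terminal codon absent or not a stop), ``short`` (protein under 15 aa
    excluding the stop), ``undetermined`` (non-ACGT character anywhere).
    """
    kept: list[TranscriptRecord] = []
    log: list[dict] = []
    for rec in records:
        reason = None
        if set(rec.cds) - _ACGT or set(rec.downstream) - _ACGT:
            reason = "undetermined"
        elif len(rec.cds) == 0 or len(rec.cds) % 3 != 0:
            reason = "frame"
        elif rec.cds[-3:] not in STOP_CODONS:
            reason = "stop"
        elif len(rec.cds) // 3 - 1 < MIN_PROTEIN_AA:
            reason = "short"
        if reason is None:
            kept.append(rec)
        else:
            log.append({"id": rec.id, "reason": reason})
    return kept, pd.DataFrame(log, columns=["id", "reason"])


def terminus_key(rec: TranscriptRecord) -> str:
    """Dedup key: last 45 CDS nt plus up to 303 nt downstream."""
    return rec.cds[-45:] + rec.downstream[:303]


def dedupe_termini(
    records: list[TranscriptRecord],
) -> tuple[list[TranscriptRecord], dict[str, tuple[str, ...]]]:
    """One representative (lexicographically smallest id) per identical
    3' terminus; returns (representatives, representative id -> all ids)."""
    groups: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        groups.setdefault(terminus_key(rec), []).append(rec)
    reps: list[TranscriptRecord] = []
    agg: dict[str, tuple[str, ...]] = {}
    for members in groups.values():
        members = sorted(members, key=lambda r: r.id)
        reps.append(members[0])
        agg[members[0].id] = tuple(r.id for r in members)
    reps.sort(key=lambda r: r.id)
    return reps, agg


def find_extension(rec: TranscriptRecord) -> ExtensionCandidate:
    """Locate the readthrough extension behind a transcript's stop codon.

    The extension runs from the first downstream codon to the next in-frame
    stop (exclusive); its translation is prefixed with 'X' for the recoded
    annotated stop.  Without an in-frame stop inside the 300-nt window the
    candidate carries no extension.
    """
    if len(rec.downstream) < 6:
        raise ValueError(
            f"{rec.id}: need >= 6 nt downstream to assemble the stop-codon context"
        )
    scc = StopCodonContext(
        upstream=rec.cds[-9:-3], stop=rec.cds[-3:], downstream=rec.downstream[:6]
    )
    window = rec.downstream[:MAX_DOWNSTREAM]
    ext_nt = None
    for i in range(0, len(window) - 2, 3):
        if window[i : i + 3] in STOP_CODONS:
            ext_nt = window[:i]
            break
    if ext_nt is None:
        return ExtensionCandidate(id=rec.id, scc=scc, extension_nt=None,
                                  extension_aa=None, cterm=None)
    ext_aa = "X" + str(Seq(ext_nt).translate())
    protein = str(Seq(rec.cds[:-3]).translate())
    cterm = (protein + ext_aa)[-WINDOW:]
    return ExtensionCandidate(
        id=rec.id, scc=scc, extension_nt=ext_nt, extension_aa=ext_aa, cterm=cterm
    )


def scale_rtp_unit(scores: list[float] | np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant input scales to all zeros."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score list")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def rank_candidates(
    candidates: list[ExtensionCandidate],
    rtp_models: dict[str, RidgeModel],
    pts1_model: RLSCModel,
    product_rtp_model: str = "LINiter",
) -> tuple[list[ExtensionCandidate], int]:
    """Score and rank candidates by RTP+ x PTS1 posterior.

    RTP+ scaling is computed over the scanned set, so ranks depend on the
    input universe.  Candidates without an extension keep PTS1 posterior 0
    and therefore product 0.  Returns the ranked list and the half-max
    rank: the first rank whose product falls below 50% of the maximum.
    """
    if product_rtp_model not in rtp_models:
        raise KeyError(f"no RTP model named {product_rtp_model!r} supplied")
    for cand in candidates:
        cand.rtp = {name: rtp_score(m, cand.scc).rtp for name, m in rtp_models.items()}
        cand.pts1_posterior = (
            posterior(pts1_model, cand.cterm) if cand.cterm is not None else 0.0
        )
    plus = scale_rtp_unit([c.rtp[product_rtp_model] for c in candidates])
    for cand, rp in zip(candidates, plus):
        cand.rtp_plus = float(rp)
        cand.product_score = cand.rtp_plus * cand.pts1_posterior
    ranked = sorted(candidates, key=lambda c: (-c.product_score, c.id))
    for i, cand in enumerate(ranked, start=1):
        cand.rank = i
    half = ranked[0].product_score / 2.0
    half_max_rank = next(
        (c.rank for c in ranked if c.product_score < half), len(ranked) + 1
    )
    return ranked, half_max_rank


def scan_transcriptome(
    records: list[TranscriptRecord],
    rtp_models: dict[str, RidgeModel],
    pts1_model: RLSCModel,
    product_rtp_model: str = "LINiter",
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Full pipeline: filter, dedupe, extend, score, rank.

    Returns (ranked results table, removal log, half-max rank).
    """
    kept, removal_log = filter_transcripts(records)
    reps, agg = dedupe_termini(kept)
    candidates = []
    for rec in reps:
        cand = find_extension(rec)
        cand.aggregated_ids = agg[rec.id]
        candidates.append(cand)
    ranked, half_max_rank = rank_candidates(
        candidates, rtp_models, pts1_model, product_rtp_model
    )
    rows = []
    for c in ranked:
        row = {
            "id": c.id,
            "scc": c.scc.text,
            "extension_nt": c.extension_nt if c.extension_nt is not None else "",
            "extension_aa": c.extension_aa if c.extension_aa is not None else "",
            **{f"rtp_{name}": c.rtp[name] for name in rtp_models},
            "rtp_plus": c.rtp_plus,
            "pts1_posterior": c.pts1_posterior,
            "product_score": c.product_score,
            "rank": c.rank,
            "aggregated_ids": ",".join(c.aggregated_ids),
        }
        rows.append(row)
    return pd.DataFrame(rows), removal_log, half_max_rank


@dataclass(frozen=True)
class MotifPattern:
    """A stop-codon-context pattern, e.g. stop TGA with CTA at +4..+6."""

    stop: str
    bases: tuple[tuple[int, str], ...]  # (position, required base)

    def __post_init__(self) -> None:
        if self.stop not in STOP_CODONS:
            raise ValueError(f"impossible stop codon {self.stop!r} in pattern")
        for p, b in self.bases:
            if not (-6 <= p <= -1 or 4 <= p <= 9):
                raise ValueError(f"pattern position {p} outside the context window")
            if b not in _ACGT:
                raise ValueError(f"pattern base {b!r} not in ACGT")

    def matches(self, scc: StopCodonContext) -> bool:
        if scc.stop != self.stop:
            return False
        return all(scc.base_at(p) == b for p, b in self.bases)


#: The high-readthrough consensus patterns (UGA CUA and UGA CUA G).
UGA_CUA = MotifPattern(stop="TGA", bases=((4, "C"), (5, "T"), (6, "A")))
UGA_CUA_G = MotifPattern(stop="TGA", bases=((4, "C"), (5, "T"), (6, "A"), (7, "G")))


def motif_count(records: list[TranscriptRecord], pattern: MotifPattern) -> int:
    """Count representatives whose stop-codon context matches the pattern."""
    total = 0
    for rec in records:
        if len(rec.downstream) < 6:
            continue
        scc = StopCodonContext(
            upstream=rec.cds[-9:-3], stop=rec.cds[-3:], downstream=rec.downstream[:6]
        )
        if pattern.matches(scc):
            total += 1
    return total


# ---------------------------------------------------------------------------
# FASTA input: CDS+downstream concatenated, with a companion CDS-length table

def read_transcripts_fasta(fasta_path, cds_lengths: dict[str, int] | None = None,
                           downstream_length: int | None = None) -> list[TranscriptRecord]:
    """Load records from FASTA where each sequence is CDS plus downstream.

    The split point comes either from ``cds_lengths`` (id -> CDS length,
    e.g. read from a TSV) or from a fixed ``downstream_length`` suffix.
    """
    from Bio import SeqIO

    if (cds_lengths is None) == (downstream_length is None):
        raise ValueError("provide exactly one of cds_lengths or downstream_length")
    records = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        s = str(seq_rec.seq).upper()
        if cds_lengths is not None:
            if seq_rec.id not in cds_lengths:
                raise KeyError(f"no CDS length for {seq_rec.id}")
            split = cds_lengths[seq_rec.id]
        else:
            split = len(s) - downstream_length
        records.append(TranscriptRecord(id=seq_rec.id, cds=s[:split], downstream=s[split:]))
    return records
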