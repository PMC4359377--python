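"""Synthetic datasets with the statistical structure each stage assumes.

Three generators cover the pipeline's inputs end to end: stop-codon
context training sets with a planted linear weight structure plus Gaussian
response noise; separable peptide sets with planted PTS1 tripeptide motifs
against motif-free negatives; and toy transcriptomes seeded with
high-readthrough (UGA CUA G) candidates carrying a PTS1-bearing extension
among motif-free decoys.  All generators are pure functions of their
arguments including the seed.

The published experiment tables (contexts with measured readthrough,
model weights, context base frequencies) are bundled as fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .context import BASES, CONTEXT_POSITIONS, STOP_CODONS, StopCodonContext
from .pts1 import AMINO_ACIDS, LabeledPeptideSet
from .ridge import RidgeModel, TrainingSet, design_matrix
from .scan import TranscriptRecord

# ---------------------------------------------------------------------------
# SCC training sets

@dataclass
class SyntheticSCCSet:
    train: TrainingSet
    planted: RidgeModel
    noise_sd: float
    seed: int
    n_clipped: int  # responses truncated at 0 (readthrough is non-negative)


def random_context(rng: np.random.Generator) -> StopCodonContext:
    """A context uniform per position; stop uniform over the three codons."""
    nt = rng.choice(list(BASES), size=12)
    return StopCodonContext(
        upstream="".join(nt[:6]),
        stop=str(rng.choice(list(STOP_CODONS))),
        downstream="".join(nt[6:]),
    )


def random_planted_model(
    positions=CONTEXT_POSITIONS, seed: int = 0, scale: float = 1.0
) -> RidgeModel:
    """Random non-negative planted weights in identifiable form.

    Because every encoded context activates exactly one entry per block,
    indicator weights are only determined up to a constant shift per
    block; the least-squares solution is the representative whose block
    sums are all equal.  Planted weights are therefore drawn uniform and
    rescaled so each position block (and the stop block) sums to ``scale``
    — non-negative, so the linear response stays >= 0, and exactly
    recoverable by an unregularised fit on noise-free data.
    """
    rng = np.random.default_rng(seed)
    pos = tuple(positions)
    cw: dict[tuple[int, str], float] = {}
    for p in pos:
        raw = rng.uniform(0.1, 1.0, size=4)
        raw *= scale / raw.sum()
        for b, w in zip(BASES, raw):
            cw[(p, b)] = float(w)
    raw = rng.uniform(0.1, 1.0, size=3)
    raw *= scale / raw.sum()
    sw = {s: float(w) for s, w in zip(STOP_CODONS, raw)}
    return RidgeModel(positions=pos, context_weights=cw, stop_weights=sw, k=0.0)


def gen_scc_dataset(
    n: int,
    planted: RidgeModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticSCCSet:
    """Contexts with response y = w_planted . x_normalised + Gaussian noise.

    Responses are truncated at 0 (a readthrough fraction cannot be
    negative); with non-negative planted weights and modest noise this is
    rare, and ``n_clipped`` records how often it happened.
    """
    if n < 2:
        raise ValueError("need n >= 2 synthetic contexts")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if planted is None:
        planted = random_planted_model(seed=seed)
    contexts = [random_context(rng) for _ in range(n)]
    X = design_matrix(contexts, planted.positions)
    y = X @ planted.weight_vector()
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    clipped = int(np.sum(y < 0))
    y = np.clip(y, 0.0, None)
    return SyntheticSCCSet(
        train=TrainingSet(contexts=contexts, y=y),
        planted=planted,
        noise_sd=noise_sd,
        seed=seed,
        n_clipped=clipped,
    )


# ---------------------------------------------------------------------------
# PTS1 peptide sets

DEFAULT_PTS1_MOTIFS = ("SKL", "SRL", "ARL", "AKL")

def is_pts1_like(cterm: str) -> bool:
    """PTS1-like terminus: canonical tripeptide neighbourhood.

    The consensus is (S/A/C)(K/R/H)(L/M); a terminal L/M with either a
    basic residue at -2 or a small residue at -3 already resembles a weak
    signal, so negatives and decoys avoid the whole neighbourhood.
    """
    if len(cterm) < 3:
        return False
    if cterm[-1] not in "LM":
        return False
    return cterm[-2] in "KRH" or cterm[-3] in "SAC"


@dataclass
class SyntheticPeptideSet:
    data: LabeledPeptideSet
    motifs: tuple[str, ...]
    seed: int


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def gen_pts1_dataset(
    n_pos: int,
    n_neg: int,
    motifs: tuple[str, ...] = DEFAULT_PTS1_MOTIFS,
    seed: int = 0,
    min_len: int = 10,
    max_len: int = 15,
) -> SyntheticPeptideSet:
    """Positives end in a sampled motif tripeptide; negatives avoid every
    motif (and the broader PTS1-like [SAC][KRH]L family when possible)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one example per class")
    motifs = tuple(m.upper() for m in motifs)
    if len(set(motifs)) >= len(AMINO_ACIDS) ** 3:
        raise ValueError("motif list covers every tripeptide: no valid negatives")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    labels: list[int] = []
    for _ in range(n_pos):
        length = int(rng.integers(min_len, max_len + 1))
        body = _random_peptide(rng, length - 3)
        seqs.append(body + str(rng.choice(motifs)))
        labels.append(1)
    for _ in range(n_neg):
        for _attempt in range(1000):
            length = int(rng.integers(min_len, max_len + 1))
            pep = _random_peptide(rng, length)
            if pep[-3:] not in motifs and not is_pts1_like(pep):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample a motif-free negative")
        seqs.append(pep)
        labels.append(-1)
    return SyntheticPeptideSet(
        data=LabeledPeptideSet(sequences=seqs, labels=np.array(labels)),
        motifs=motifs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Toy transcriptomes

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _STANDARD_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()

_SENSE_CODONS = sorted(_STANDARD_TABLE.forward_table)


@dataclass
class PlantedCandidate:
    """A high-readthrough candidate planted into the toy transcriptome.

    Defaults mimic the LDHB arrangement: a UGA stop followed by CUA G
    (the high-RTP consensus) and an 18-nt extension encoding six residues
    that end in the cryptic PTS1 tripeptide SRL.
    """

    stop: str = "TGA"
    extension_peptide: str = "LASSRL"
    scc_downstream: str = "CTAG"  # required nucleotides at +4 onward

    def extension_nt(self, rng: np.random.Generator) -> str:
        codons = []
        for i, aa in enumerate(self.extension_peptide):
            options = _AA_TO_CODONS[aa]
            want = self.scc_downstream[3 * i : 3 * i + 3]
            if want:
                options = [c for c in options if c.startswith(want)]
                if not options:
                    raise ValueError(
                        f"motif {self.scc_downstream!r} is inconsistent with "
                        f"residue {aa!r} at extension position {i + 1}"
                    )
            codons.append(str(rng.choice(options)))
        return "".join(codons)


@dataclass
class SyntheticTranscriptome:
    records: list[TranscriptRecord]
    planted_ids: tuple[str, ...]
    seed: int


def _random_cds(rng: np.random.Generator, n_codons: int, stop: str) -> str:
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    return body + stop


def gen_transcriptome(
    n_decoys: int,
    planted: list[PlantedCandidate] | None = None,
    seed: int = 0,
    downstream_length: int = 300,
    min_codons: int = 30,
    max_codons: int = 80,
) -> SyntheticTranscriptome:
    """Motif-free decoys plus planted readthrough candidates.

    Decoys never carry the UGA CUA stop-codon motif, and any extension they
    happen to have never terminates in a PTS1-like tripeptide; every record
    passes the scan filters by construction.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if planted is None:
        planted = [PlantedCandidate()]
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    planted_ids: list[str] = []

    for i, spec in enumerate(planted):
        ext = spec.extension_nt(rng)
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        cds = _random_cds(rng, n_codons, spec.stop)
        tail_len = downstream_length - len(ext) - 3
        tail = "".join(rng.choice(list(BASES), size=tail_len))
        rec = TranscriptRecord(
            id=f"planted_{i:04d}", cds=cds, downstream=ext + "TAA" + tail
        )
        records.append(rec)
        planted_ids.append(rec.id)

    for i in range(n_decoys):
        while True:
            stop = str(rng.choice(list(STOP_CODONS)))
            n_codons = int(rng.integers(min_codons, max_codons + 1))
            cds = _random_cds(rng, n_codons, stop)
            down = "".join(rng.choice(list(BASES), size=downstream_length))
            if stop == "TGA" and down.startswith("CTA"):
                continue  # would carry the high-readthrough motif
            if _decoy_extension_is_pts1_like(cds, down):
                continue
            break
        records.append(TranscriptRecord(id=f"decoy_{i:05d}", cds=cds, downstream=down))

    return SyntheticTranscriptome(
        records=records, planted_ids=tuple(planted_ids), seed=seed
    )


def _decoy_extension_is_pts1_like(cds: str, downstream: str) -> bool:
    from Bio.Seq import Seq

    for i in range(0, len(downstream) - 2, 3):
        if downstream[i : i + 3] in STOP_CODONS:
            ext = downstream[:i]
            protein = str(Seq(cds[:-3]).translate())
            cterm = protein + "X" + str(Seq(ext).translate())
            return is_pts1_like(cterm)
    return False


# ---------------------------------------------------------------------------
# Bundled fixtures

_FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "table3": "table3.tsv",
    "table3_stop": "table3_stop.tsv",
}


def fixtures(name: str) -> pd.DataFrame:
    """Bundled verbatim transcriptions of the published tables.

    ``table1``: measured dual-reporter readthrough contexts; ``table2``:
    LINiter/LINfs3 regression weights (long format); ``table3``: context
    base frequencies (``table3_stop`` for the stop-codon frequencies).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    path = resources.files("readthrough.data") / _FIXTURE_FILES[name]
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def table1_training_set() -> TrainingSet:
    """The bundled measured contexts as a ready-to-fit training set."""
    from .context import parse_scc

    tab = fixtures("table1")
    contexts = [parse_scc(t, flank=10) for t in tab["scc_text"]]
    return TrainingSet(contexts=contexts, y=tab["readthrough_pct"].to_numpy())
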