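"""Stop-codon contexts and their indicator-vector encoding.

A stop-codon context (SCC) is the 15-nt window covering the stop codon
(positions +1..+3) together with six nucleotides upstream (-6..-1) and six
downstream (+4..+9).  Contexts are encoded as sparse binary indicator
vectors: four entries per context position (one per base, A/C/G/T) and
three entries for the stop codon, which is treated as a single three-way
categorical position (TAA/TAG/TGA) rather than three nucleotide positions.
A full-context vector therefore lives in 12 * 4 + 3 = 51 dimensions.

Feature vectors are normalised to Euclidean unit length before regression,
which for binary vectors amounts to dividing by the square root of the
number of active positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical context-position order used for all vector layouts.
CONTEXT_POSITIONS: tuple[int, ...] = (-6, -5, -4, -3, -2, -1, 4, 5, 6, 7, 8, 9)

BASES = "ACGT"
STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")

#: Dimensionality of the full indicator encoding (12 positions x 4 bases + 3 stops).
FULL_DIM = 4 * len(CONTEXT_POSITIONS) + len(STOP_CODONS)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_POSITION_INDEX = {p: i for i, p in enumerate(CONTEXT_POSITIONS)}
_STOP_INDEX = {s: i for i, s in enumerate(STOP_CODONS)}


def _canonical_nt(text: str, what: str) -> str:
    s = text.upper().replace("U", "T")
    bad = set(s) - set(BASES)
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)} in {what}: {text!r}")
    return s


@dataclass(frozen=True)
class StopCodonContext:
    """The -6..+9 nucleotide neighbourhood of a stop codon.

    RNA input (U) is canonicalised to T on construction; the internal
    alphabet is DNA.
    """

    upstream: str
    stop: str
    downstream: str

    def __post_init__(self) -> None:
        up = _canonical_nt(self.upstream, "upstream flank")
        down = _canonical_nt(self.downstream, "downstream flank")
        stop = self.stop.upper().replace("U", "T")
        if len(up) != 6 or len(down) != 6:
            raise ValueError(
                f"flanks must be exactly 6 nt, got {len(up)} upstream / {len(down)} downstream"
            )
        if stop not in STOP_CODONS:
            raise ValueError(f"stop triplet {self.stop!r} not one of {STOP_CODONS}")
        object.__setattr__(self, "upstream", up)
        object.__setattr__(self, "stop", stop)
        object.__setattr__(self, "downstream", down)

    def base_at(self, position: int) -> str:
        """Base at a context position (-6..-1 upstream, +4..+9 downstream)."""
        if -6 <= position <= -1:
            return self.upstream[position + 6]
        if 4 <= position <= 9:
            return self.downstream[position - 4]
        raise ValueError(f"position {position} is not a context position")

    @property
    def text(self) -> str:
        """Context as ``UPSTREAM STOP DOWNSTREAM`` (spaced dialect, flank 6)."""
        return f"{self.upstream} {self.stop} {self.downstream}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class ContextVector:
    """Indicator encoding of a context over a declared position subset.

    ``entries`` always has the full 51-entry layout (12 four-entry base
    blocks in canonical position order, then the three stop indicators);
    blocks for positions outside ``active_positions`` are all zero.
    """

    entries: np.ndarray
    active_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (FULL_DIM,):
            raise ValueError(f"expected {FULL_DIM} entries, got {e.shape}")
        object.__setattr__(self, "entries", e)
        object.__setattr__(self, "active_positions", tuple(self.active_positions))

    def subvector(self) -> np.ndarray:
        """Compact vector over the active blocks only (4p + 3 entries)."""
        idx: list[int] = []
        for p in self.active_positions:
            base = 4 * _POSITION_INDEX[p]
            idx.extend(range(base, base + 4))
        idx.extend(range(48, 51))
        return self.entries[idx]


def parse_scc(text: str, flank: int = 10) -> StopCodonContext:
    """Parse a context string with the stop triplet centred per ``flank``.

    Whitespace is ignored.  ``flank`` is the number of nucleotides on each
    side of the stop (reporter constructs typically use flank 10); flanks wider
    than 6
    are trimmed symmetrically to the modelled -6..+9 window.
    """
    s = "".join(text.split())
    if flank < 6:
        raise ValueError(f"flank {flank} < 6: insufficient flanks for a -6..+9 context")
    expected = 2 * flank + 3
    if len(s) != expected:
        raise ValueError(
            f"insufficient flanks: expected {expected} nt for flank {flank}, got {len(s)}"
        )
    s = _canonical_nt(s, "context")
    stop = s[flank : flank + 3]
    if stop not in STOP_CODONS:
        raise ValueError(f"central triplet {stop!r} is not a stop codon")
    return StopCodonContext(
        upstream=s[flank - 6 : flank],
        stop=stop,
        downstream=s[flank + 3 : flank + 9],
    )


def encode(
    ctx: StopCodonContext, positions: Sequence[int] = CONTEXT_POSITIONS
) -> ContextVector:
    """Indicator-encode a context over ``positions`` (stop always included)."""
    pos = tuple(sorted(set(positions), key=_POSITION_INDEX.__getitem__))
    unknown = [p for p in positions if p not in _POSITION_INDEX]
    if unknown:
        raise ValueError(f"unknown context positions {unknown}")
    v = np.zeros(FULL_DIM)
    for p in pos:
        v[4 * _POSITION_INDEX[p] + _BASE_INDEX[ctx.base_at(p)]] = 1.0
    v[48 + _STOP_INDEX[ctx.stop]] = 1.0
    return ContextVector(entries=v, active_positions=pos)


def decode(vec: ContextVector) -> StopCodonContext:
    """Invert a full 13-position encoding back to its context."""
    if tuple(vec.active_positions) != CONTEXT_POSITIONS:
        raise ValueError("only full-context vectors decode uniquely")
    bases = {}
    ref = vec.entries / max(vec.entries.max(), np.finfo(float).tiny)
    for p in CONTEXT_POSITIONS:
        block = ref[4 * _POSITION_INDEX[p] : 4 * _POSITION_INDEX[p] + 4]
        (on,) = np.flatnonzero(block == 1.0)
        bases[p] = BASES[on]
    (stop_on,) = np.flatnonzero(ref[48:51] == 1.0)
    return StopCodonContext(
        upstream="".join(bases[p] for p in range(-6, 0)),
        stop=STOP_CODONS[stop_on],
        downstream="".join(bases[p] for p in range(4, 10)),
    )


def unit_normalize(vec: ContextVector) -> np.ndarray:
    """Scale the indicator vector to Euclidean unit length.

    For a binary vector this divides by sqrt(number of active positions).
    """
    norm = float(np.linalg.norm(vec.entries))
    if norm == 0.0:
        raise ValueError("cannot normalise an all-zero vector")
    return vec.entries / norm


def base_frequencies(
    contexts: Iterable[StopCodonContext],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-position base frequencies and stop-codon frequencies.

    Returns a (12 positions x A,C,G,T) DataFrame whose rows each sum to 1,
    and a 3-entry Series over TAA/TAG/TGA summing to 1.
    """
    ctxs = list(contexts)
    if not ctxs:
        raise ValueError("empty context list")
    counts = np.zeros((len(CONTEXT_POSITIONS), 4))
    stop_counts = np.zeros(3)
    for c in ctxs:
        for i, p in enumerate(CONTEXT_POSITIONS):
            counts[i, _BASE_INDEX[c.base_at(p)]] += 1
        stop_counts[_STOP_INDEX[c.stop]] += 1
    freq = pd.DataFrame(
        counts / len(ctxs), index=list(CONTEXT_POSITIONS), columns=list(BASES)
    )
    freq.index.name = "position"
    stop_freq = pd.Series(
        stop_counts / len(ctxs), index=list(STOP_CODONS), name="frequency"
    )
    return freq, stop_freq


# ---------------------------------------------------------------------------
# Tabular I/O (spaced dialect: "NNNNNNNNNN SSS NNNNNNNNNN")

def read_context_table(path, flank: int | None = None) -> pd.DataFrame:
    """Read a TSV of contexts with columns context_id, scc_text and optional
    readthrough_pct / readthrough_sd; adds a parsed ``context`` column.

    When ``flank`` is None it is inferred per row from the text length
    (reporter constructs are flank 10; internally stored contexts flank 6).
    """
    df = pd.read_csv(path, sep="\t", dtype={"context_id": str, "scc_text": str})
    if not {"context_id", "scc_text"} <= set(df.columns):
        raise ValueError("context table needs columns context_id and scc_text")
    df = df.copy()

    def _parse(text: str) -> StopCodonContext:
        f = flank if flank is not None else (len("".join(text.split())) - 3) // 2
        return parse_scc(text, flank=f)

    df["context"] = [_parse(t) for t in df["scc_text"]]
    return df


def write_context_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("context_id", "scc_text", "readthrough_pct", "readthrough_sd") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def write_frequency_table(freq: pd.DataFrame, stop_freq: pd.Series, path) -> None:
    """Write per-position and stop frequencies as one TSV (stop row last)."""
    out = freq.round(4).reset_index()
    out["position"] = out["position"].astype(str)
    with open(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False)
        fh.write("# stop codon frequencies: " + "\t".join(
            f"{s}={stop_freq[s]:.4f}" for s in STOP_CODONS) + "\n")
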