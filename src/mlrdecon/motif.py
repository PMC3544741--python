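"""ERE motif matrix construction and matrix-similarity promoter scanning.

The EGR family of zinc-finger transcription factors (Egr1-4, plus WT1 and
CKROX) share a GC-rich response element with consensus GCG(G/T)GGGCG.  This
module builds an open position-frequency matrix from that consensus and
scores promoter windows with a conservation-weighted matrix-similarity
statistic: each position contributes its base frequency weighted by the
position's information content, normalized so the optimal sequence scores
exactly 1.  A window is called a site when its similarity reaches the scan
threshold (0.80 by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes -> allowed bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifMatrix:
    """Position-frequency matrix with information-content weights.

    ``freq`` is (width, 4) over A/C/G/T, each row summing to 1; ``weights``
    are the per-position information contents in bits,
    ``w_i = 2 + sum_b f(i,b) log2 f(i,b)`` with 0*log0 = 0.
    """

    name: str
    freq: np.ndarray
    consensus: str

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("freq must be a (width, 4) array")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each frequency row must sum to 1")
        object.__setattr__(self, "freq", f)

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def weights(self) -> np.ndarray:
        f = self.freq
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(f > 0, f * np.log2(f), 0.0)
        return 2.0 + h.sum(axis=1)

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(
            name=self.name + "_rc",
            freq=self.freq[::-1, ::-1].copy(),
            consensus=reverse_complement(self.consensus),
        )

    def sample_consensus(self, rng: np.random.Generator) -> str:
        """One realization of the consensus, degenerate codes resolved
        uniformly at random."""
        return "".join(allowed[rng.integers(len(allowed))]
                       for allowed in (IUPAC[c] for c in self.consensus))

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "consensus": self.consensus,
             "bases": BASES, "freq": self.freq.tolist(),
             "weights": self.weights.tolist()},
            indent=2,
        )


def build_ere_matrix(consensus: str = "GCGKGGGCG", consensus_weight: float = 0.85,
                     name: str = "ERE") -> MotifMatrix:
    """Build the ERE position-frequency matrix from an IUPAC consensus.

    Non-degenerate positions put ``consensus_weight`` on the consensus base
    and spread the remainder evenly over the other three; degenerate
    positions split ``consensus_weight`` evenly over their allowed bases.
    """
    if not 0.0 < consensus_weight < 1.0:
        raise ValueError("consensus_weight must lie in (0, 1)")
    freq = np.empty((len(consensus), 4))
    for i, code in enumerate(consensus.upper()):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r} at position {i}")
        # disallowed bases always get the pseudo-frequency (1 - w)/3;
        # allowed bases split the remaining mass evenly (w for a unique
        # consensus base, e.g. 0.45/0.45 for a two-base degeneracy)
        off = (1.0 - consensus_weight) / 3.0
        row = np.full(4, off)
        n_allowed = len(allowed)
        share = (1.0 - off * (4 - n_allowed)) / n_allowed
        for b in allowed:
            row[_BASE_INDEX[b]] = share
        freq[i] = row / row.sum()
    return MotifMatrix(name=name, freq=freq, consensus=consensus.upper())


@dataclass(frozen=True)
class MotifMatch:
    """One scoring window: 0-based half-open coordinates on the forward
    strand of the scanned sequence."""

    sequence_id: str
    offset: int
    strand: str
    similarity: float
    matched_window: str


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; ambiguous characters get 4 (frequency 0)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def matrix_similarity(window: str, matrix: MotifMatrix) -> float:
    """Conservation-weighted similarity of one window to the matrix.

    ``sum_i w_i f(i, b_i) / sum_i w_i max_b f(i, b)`` — 1 exactly when every
    base attains its per-position maximum.  Ambiguous bases score frequency 0
    at their position.
    """
    if len(window) != matrix.width:
        raise ValueError("window length must equal matrix width")
    idx = _encode(window)
    if (idx == 4).any():
        log.warning("ambiguous base in window %r scored as frequency 0", window)
    w = matrix.weights
    f = np.hstack([matrix.freq, np.zeros((matrix.width, 1))])
    num = float((w * f[np.arange(matrix.width), idx]).sum())
    den = float((w * matrix.freq.max(axis=1)).sum())
    return num / den


def _scores_one_strand(idx: np.ndarray, matrix: MotifMatrix) -> np.ndarray:
    """Similarity of every window of an encoded sequence, vectorized."""
    width = matrix.width
    if idx.size < width:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(idx, width)
    w = matrix.weights
    f = np.hstack([matrix.freq, np.zeros((width, 1))])
    num = (w[None, :] * f[np.arange(width)[None, :], wins]).sum(axis=1)
    den = (w * matrix.freq.max(axis=1)).sum()
    return num / den


def scan_sequence(
    seq: str,
    matrix: MotifMatrix,
    threshold: float = 0.80,
    both_strands: bool = True,
    sequence_id: str = "seq",
) -> list[MotifMatch]:
    """All windows scoring >= threshold, on the + strand and (optionally) the
    - strand via the reverse-complement of each window.

    Coordinates are 0-based half-open on the input's forward strand for both
    strands.  A sequence shorter than the matrix yields an empty result.
    """
    seq = seq.upper()
    if len(seq) < matrix.width:
        log.warning("sequence %s shorter than motif width; no windows", sequence_id)
        return []
    idx = _encode(seq)
    matches: list[MotifMatch] = []
    plus = _scores_one_strand(idx, matrix)
    for off in np.flatnonzero(plus >= threshold):
        off = int(off)
        matches.append(MotifMatch(sequence_id, off, "+", float(plus[off]),
                                  seq[off : off + matrix.width]))
    if both_strands:
        # scoring the forward windows against the reverse-complement matrix
        # equals scoring each window's reverse complement against the matrix
        minus = _scores_one_strand(idx, matrix.reverse_complement())
        for off in np.flatnonzero(minus >= threshold):
            off = int(off)
            matches.append(MotifMatch(sequence_id, off, "-", float(minus[off]),
                                      seq[off : off + matrix.width]))
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


def scan_records(records, matrix: MotifMatrix, threshold: float = 0.80,
                 both_strands: bool = True) -> list[MotifMatch]:
    out: list[MotifMatch] = []
    for rec in records:
        out.extend(scan_sequence(str(rec.seq), matrix, threshold, both_strands,
                                 sequence_id=rec.id))
    return out


def fraction_with_site(
    fasta, matrix: MotifMatrix, threshold: float = 0.80, both_strands: bool = True
) -> tuple[float, pd.DataFrame]:
    """Fraction of FASTA records containing at least one site, plus a
    per-record match-count table.

    ``fasta`` may be a path or an iterable of SeqRecords.
    """
    if isinstance(fasta, (str, bytes)) or hasattr(fasta, "read"):
        records = list(SeqIO.parse(fasta, "fasta"))
    else:
        records = list(fasta)
    if not records:
        raise ValueError("no FASTA records to scan")
    counts = {}
    for rec in records:
        hits = scan_sequence(str(rec.seq), matrix, threshold, both_strands, rec.id)
        counts[rec.id] = len(hits)
    table = pd.DataFrame(
        {"n_sites": pd.Series(counts)},
    ).rename_axis("sequence_id")
    table["has_site"] = table["n_sites"] > 0
    return float(table["has_site"].mean()), table


def matches_to_bed(matches: list[MotifMatch], matrix: MotifMatrix) -> pd.DataFrame:
    """BED-like table: sequence_id, start, end, name, score 0-1000, strand."""
    return pd.DataFrame(
        [
            {
                "sequence_id": m.sequence_id,
                "start": m.offset,
                "end": m.offset + matrix.width,
                "name": matrix.name,
                "score": int(round(m.similarity * 1000)),
                "strand": m.strand,
            }
            for m in matches
        ],
        columns=["sequence_id", "start", "end", "name", "score", "strand"],
    )
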