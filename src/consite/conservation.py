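"""Per-residue sequence conservation as a Jensen-Shannon divergence.

The conservation score of a residue (C_score) is the Jensen-Shannon
divergence, in bits by default, between the position's amino-acid frequency
distribution P and a background distribution Q:

    JSD(P, Q) = 1/2 KL(P || M) + 1/2 KL(Q || M),   M = (P + Q) / 2

so 0 <= C_score <= 1 with log base 2; 0 means the position looks like
background, 1 means perfectly conserved on letters the background never
shows.  Position frequencies come either from the weighted-observed-
percentage block of a PSI-BLAST ASCII PSSM or from a FASTA multiple
sequence alignment.  The default background is the BLOSUM62 marginal
frequency table; a uniform background is available.

Sequence positions are mapped onto structure residues by global alignment
of the profile's query sequence against the chain's observed residue
sequence; residues that do not align (e.g. engineered tags) are flagged and
given the chain median score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


class PSSMFormatError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM or alignment input."""


class MappingError(ValueError):
    """Profile query sequence does not match the structure chain."""


@dataclass
class BackgroundDistribution:
    frequencies: np.ndarray  # (20,), strictly positive, sums to 1

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (20,) or np.any(f <= 0):
            raise ValueError("background must be 20 strictly positive frequencies")
        self.frequencies = f / f.sum()


@dataclass
class SequenceProfile:
    """Per-position amino-acid frequencies plus the query sequence."""

    query: str
    frequencies: np.ndarray  # (L, 20), rows sum to 1


@dataclass
class ConservationProfile:
    chain_id: str
    c_scores: dict[tuple[int, str], float]  # (residue_seq, icode) -> C_score
    unaligned: set[tuple[int, str]] = field(default_factory=set)

    def score_by_residue_index(self, residues) -> np.ndarray:
        return np.array([self.c_scores[(r.residue_seq, r.icode)] for r in residues])


def load_background(name: str | Path = "blosum62") -> BackgroundDistribution:
    """'blosum62', 'uniform', or a path to a 20-row letter/frequency table."""
    if name == "uniform":
        return BackgroundDistribution(np.full(20, 1.0 / 20))
    if name == "blosum62":
        text = resources.files("consite.data").joinpath(
            "background_blosum62.dat").read_text()
    else:
        text = Path(name).read_text()
    freqs = np.zeros(20)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        letter, value = line.split()
        freqs[AA_INDEX[letter]] = float(value)
    if np.any(freqs <= 0):
        raise ValueError("background table must cover all 20 amino acids")
    return BackgroundDistribution(freqs)


# ---------------------------------------------------------------------------
# input parsing


def parse_pssm(
    path: str | Path, background: BackgroundDistribution | None = None
) -> SequenceProfile:
    """Parse a PSI-BLAST ASCII PSSM into per-position frequencies.

    Frequencies are taken from the weighted observed percentage block
    (the second group of 20 columns), divided by 100 and renormalized.
    Zero-sum rows (positions with no information) fall back to the
    background distribution.
    """
    background = background or load_background()
    lines = Path(path).read_text().splitlines()
    header_cols: list[str] | None = None
    rows: list[np.ndarray] = []
    query: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        tokens = raw.split()
        if header_cols is None:
            if len(tokens) >= 40 and all(t in AA_INDEX for t in tokens[:40]):
                header_cols = tokens
                if len(tokens) == 40:
                    pct_order = tokens[20:40]
                else:  # some writers only print the letters once
                    pct_order = tokens[:20]
            continue
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # footer (K, Lambda statistics)
        if len(tokens) < 42:
            raise PSSMFormatError(
                f"{path}:{lineno}: expected 20 log-odds and 20 percentage "
                f"columns, got {len(tokens) - 2} values"
            )
        aa = tokens[1]
        if aa not in AA_INDEX:
            raise PSSMFormatError(f"{path}:{lineno}: bad query letter {aa!r}")
        try:
            pct = np.array([float(t) for t in tokens[22:42]])
        except ValueError as exc:
            raise PSSMFormatError(f"{path}:{lineno}: {exc}") from exc
        query.append(aa)
        if pct.sum() <= 0:
            rows.append(background.frequencies.copy())
            continue
        freq = np.zeros(20)
        for col, letter in enumerate(pct_order):
            freq[AA_INDEX[letter]] += pct[col] / 100.0
        rows.append(freq / freq.sum())
    if header_cols is None or not rows:
        raise PSSMFormatError(f"{path}: not a PSI-BLAST ASCII PSSM")
    return SequenceProfile(query="".join(query), frequencies=np.vstack(rows))


def profile_from_msa(path: str | Path, pseudocount: float = 0.0) -> SequenceProfile:
    """Column frequencies of a FASTA alignment; first sequence is the query.

    Only columns where the query has a residue are kept; gaps and
    non-standard letters are excluded from the counts.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PSSMFormatError(f"{path}: empty alignment")
    length = len(records[0].seq)
    if any(len(r.seq) != length for r in records):
        raise PSSMFormatError(f"{path}: ragged alignment (unequal lengths)")
    qseq = str(records[0].seq).upper()
    rows: list[np.ndarray] = []
    query: list[str] = []
    for col in range(length):
        if qseq[col] in ("-", "."):
            continue
        counts = np.full(20, float(pseudocount))
        for rec in records:
            letter = str(rec.seq[col]).upper()
            if letter in AA_INDEX:
                counts[AA_INDEX[letter]] += 1.0
        if counts.sum() <= 0:
            raise PSSMFormatError(f"{path}: column {col + 1} has no residues")
        query.append(qseq[col] if qseq[col] in AA_INDEX else "X")
        rows.append(counts / counts.sum())
    return SequenceProfile(query="".join(query), frequencies=np.vstack(rows))


# ---------------------------------------------------------------------------
# divergence


def jensen_shannon(p: np.ndarray, q: np.ndarray, log_base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two distributions (0*log0 := 0)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same shape")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("distributions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("distributions must sum to 1")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / m[mask])))

    return (0.5 * _kl(p) + 0.5 * _kl(q)) / np.log(log_base)


# ---------------------------------------------------------------------------
# mapping onto the structure


def _align_query_to_chain(query: str, chain_seq: str) -> list[tuple[int, int]]:
    """Global alignment; returns (query_pos, chain_pos) pairs (0-based)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(query, chain_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        pairs.extend((qs + k, ts + k) for k in range(qe - qs))
    return pairs


def conservation_for_chain(
    profile: SequenceProfile,
    background: BackgroundDistribution,
    structure,
    chain_id: str,
    log_base: float = 2.0,
    min_identity: float = 0.9,
) -> ConservationProfile:
    """C_score for every residue of one chain.

    The profile's query sequence is globally aligned to the chain's observed
    residue sequence; aligned residues score JSD(position frequencies,
    background), unaligned residues are flagged and receive the chain median.

    Raises
    ------
    MappingError
        If aligned identity falls below ``min_identity``.
    """
    residues = structure.chain_residues(chain_id)
    if not residues:
        raise MappingError(f"structure has no chain {chain_id!r}")
    chain_seq = structure.chain_sequence(chain_id)
    pairs = _align_query_to_chain(profile.query, chain_seq)
    if not pairs:
        raise MappingError(f"chain {chain_id}: query does not align")
    matches = sum(profile.query[q] == chain_seq[t] for q, t in pairs)
    identity = matches / len(pairs)
    if identity < min_identity:
        raise MappingError(
            f"chain {chain_id}: query/chain identity {identity:.2f} "
            f"below {min_identity:.2f} over the aligned region"
        )

    scores: dict[tuple[int, str], float] = {}
    for q, t in pairs:
        res = residues[t]
        scores[(res.residue_seq, res.icode)] = jensen_shannon(
            profile.frequencies[q], background.frequencies, log_base=log_base
        )
    unaligned = {
        (r.residue_seq, r.icode) for r in residues
        if (r.residue_seq, r.icode) not in scores
    }
    if unaligned:
        median = float(np.median(list(scores.values())))
        for key in unaligned:
            scores[key] = median
    return ConservationProfile(chain_id=chain_id, c_scores=scores, unaligned=unaligned)
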