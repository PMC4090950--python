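"""TFBS motif counting (PWM log-odds and IUPAC regular expressions) and the
median-centered empirical enrichment test.

The enrichment test compares the observed motif count in a target sequence
set against a null distribution obtained by drawing, many times, a random
sample from a background pool matched to the targets in number and length.
Following the empirical-null convention, the null center is the *median* of
the resampled counts; the spread is the sample standard deviation, giving
Z = (observed − median)/sd and a one-sided normal p-value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PWM",
    "RegexMotif",
    "MotifNullResult",
    "SequencePool",
    "scan_pwm",
    "scan_regex",
    "empirical_motif_test",
    "reverse_complement",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T with a log-odds scorer.

    ``matrix`` has one row per motif position; each row sums to 1. Scoring
    uses log((p + pseudocount)/(1 + 4·pseudocount) / 0.25) against a uniform
    background; ambiguous bases (N) contribute a log-odds of 0.
    """

    id: str
    matrix: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4 (A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log-odds table; column 4 is the N/ambiguity column (zeros)."""
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        lo = np.log(p / 0.25)
        return np.concatenate([lo, np.zeros((self.length, 1))], axis=1)

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        # reverse positions, swap A<->T and C<->G columns
        return PWM(self.id + "_rc", self.matrix[::-1, [3, 2, 1, 0]], self.pseudocount)

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray, pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(id, counts / counts.sum(axis=1, keepdims=True), pseudocount)

    @classmethod
    def from_jaspar(cls, path: str | Path, pseudocount: float = 0.01) -> list["PWM"]:
        """Read JASPAR-style count/probability matrices via Bio.motifs."""
        from Bio import motifs as bio_motifs

        out = []
        with open(path) as fh:
            for m in bio_motifs.parse(fh, "jaspar"):
                counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
                out.append(cls.from_counts(m.matrix_id or m.name, counts, pseudocount))
        return out


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N and friends) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scan_one_strand(codes: np.ndarray, pwm: PWM, threshold: float) -> int:
    L = pwm.length
    n = codes.size - L + 1
    if n <= 0:
        return 0
    lo = pwm.log_odds
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, codes[j : j + n]]
    return int(np.count_nonzero(scores >= threshold - 1e-12))


def scan_pwm(sequence: str, pwm: PWM, threshold_frac: float = 0.8) -> int:
    """Count positions on both strands scoring >= threshold_frac · max score.

    Both strands are scanned and summed, except that a reverse-complement-
    symmetric (palindromic) matrix yields identical start positions on both
    strands, which are counted once. Sequences shorter than the motif yield 0.
    """
    codes = _encode(sequence)
    threshold = threshold_frac * pwm.max_score
    rc = pwm.reverse_complement()
    hits = _scan_one_strand(codes, pwm, threshold)
    if np.allclose(pwm.matrix, rc.matrix):
        return hits
    return hits + _scan_one_strand(codes, rc, threshold)


@dataclass(frozen=True)
class RegexMotif:
    """IUPAC-degenerate motif pattern, e.g. TGASTCA for the AP-1 site."""

    id: str
    pattern: str

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern.upper() if c not in IUPAC_CODES]
        if bad or not self.pattern:
            raise ValueError(f"invalid IUPAC code(s) {bad!r} in pattern {self.pattern!r}")

    def _regex(self, pattern: str) -> re.Pattern:
        body = "".join(
            c if len(IUPAC_CODES[c]) == 1 else f"[{IUPAC_CODES[c]}]"
            for c in pattern.upper()
        )
        return re.compile(f"(?={body})")  # lookahead -> overlapping matches

    @property
    def forward_regex(self) -> re.Pattern:
        return self._regex(self.pattern)

    @property
    def rc_pattern(self) -> str:
        return "".join(_IUPAC_COMPLEMENT[c] for c in self.pattern.upper())[::-1]


def scan_regex(sequence: str, motif: RegexMotif) -> int:
    """Count match start positions on both strands.

    The reverse-complement pattern is applied to the forward sequence; when
    the motif is its own reverse complement the two strands yield identical
    starts, which are counted once.
    """
    seq = sequence.upper()
    fwd = [m.start() for m in motif.forward_regex.finditer(seq)]
    if motif.rc_pattern == motif.pattern.upper():
        return len(fwd)
    rev = [m.start() for m in motif._regex(motif.rc_pattern).finditer(seq)]
    return len(fwd) + len(rev)


def _count_hits(seq: str, motif, threshold_frac: float) -> int:
    if isinstance(motif, PWM):
        return scan_pwm(seq, motif, threshold_frac)
    return scan_regex(seq, motif)


class SequencePool:
    """Background sequence pool with per-motif hit counts cached, so repeated
    resampling (the 1,000-replicate null) does not rescan the pool."""

    def __init__(self, sequences: Sequence[str]):
        self.sequences = [s.upper() for s in sequences]
        self.lengths = np.array([len(s) for s in self.sequences], dtype=np.int64)
        self._cache: dict[tuple, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.sequences)

    def counts(self, motif, threshold_frac: float = 0.8) -> np.ndarray:
        key = (motif.id, getattr(motif, "pattern", None) or id(motif), threshold_frac)
        if key not in self._cache:
            self._cache[key] = np.array(
                [_count_hits(s, motif, threshold_frac) for s in self.sequences]
            )
        return self._cache[key]


@dataclass
class MotifNullResult:
    """Observed motif count vs a resampled null distribution."""

    motif_id: str
    observed: int
    null_counts: np.ndarray
    mu: float  # null median
    sigma: float  # null sample standard deviation
    z: float | None
    p: float | None

    @property
    def degenerate(self) -> bool:
        return self.z is None

    def summary(self) -> str:
        if self.degenerate:
            return f"{self.motif_id}: observed={self.observed} null degenerate (sigma=0)"
        return (
            f"{self.motif_id}: observed={self.observed} mu={self.mu:g} "
            f"sigma={self.sigma:.2f} Z={self.z:.2f} p={self.p:.3g}"
        )


def empirical_motif_test(
    target_seqs: Sequence[str],
    pool: SequencePool | Sequence[str],
    motif,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    threshold_frac: float = 0.8,
    sampling: str = "auto",
) -> MotifNullResult:
    """Test motif enrichment in targets against a resampled genomic null.

    Each of ``n_reps`` replicates draws a pool sample matched to the target
    set in number and length. Two sampling schemes:

    * ``"whole"`` — whole pool sequences drawn without replacement within the
      replicate and paired to targets longest-to-longest (a drawn sequence
      longer than its matched target contributes a random substring of the
      matched length). Natural when pool members are themselves
      comparably-sized features.
    * ``"substring"`` — for each target an eligible pool sequence (length >=
      the target's) is chosen uniformly with replacement and a uniform
      substring of exactly the target length is cut, emulating random
      genomic sites of the same number and size.

    ``"auto"`` uses whole-sequence draws when pool and target lengths are
    all identical, substrings otherwise. The null center is the median and
    the spread the sample standard deviation; a zero spread flags the result
    degenerate and no p-value is emitted.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (null distribution undefined)")
    rng = np.random.default_rng(rng)
    if not isinstance(pool, SequencePool):
        pool = SequencePool(pool)
    targets = [s.upper() for s in target_seqs]
    if not targets:
        raise ValueError("empty target set")
    n = len(targets)

    target_lengths = np.sort(np.array([len(s) for s in targets]))[::-1]
    pool_counts = pool.counts(motif, threshold_frac)
    uniform = (
        pool.lengths.min() == pool.lengths.max()
        and target_lengths.min() == target_lengths.max()
        and pool.lengths[0] == target_lengths[0]
    )
    if sampling == "auto":
        sampling = "whole" if uniform else "substring"
    if sampling not in ("whole", "substring"):
        raise ValueError("sampling must be 'auto', 'whole' or 'substring'")

    observed = int(sum(_count_hits(s, motif, threshold_frac) for s in targets))

    null = np.empty(n_reps)
    if sampling == "whole":
        if n > len(pool):
            raise ValueError("pool smaller than target set; cannot sample without replacement")
        for r in range(n_reps):
            idx = rng.choice(len(pool), size=n, replace=False)
            if uniform:
                null[r] = pool_counts[idx].sum()
                continue
            drawn = idx[np.argsort(pool.lengths[idx], kind="stable")[::-1]]
            if np.any(pool.lengths[drawn] < target_lengths):
                raise ValueError("pool sequences too short for length-matched sampling")
            tot = 0
            for pi, want in zip(drawn, target_lengths):
                have = int(pool.lengths[pi])
                if have == want:
                    tot += int(pool_counts[pi])
                else:
                    start = int(rng.integers(0, have - want + 1))
                    tot += _count_hits(
                        pool.sequences[pi][start : start + want], motif, threshold_frac
                    )
            null[r] = tot
    else:
        order = np.argsort(pool.lengths, kind="stable")
        sorted_lengths = pool.lengths[order]
        first_eligible = np.searchsorted(sorted_lengths, target_lengths, side="left")
        if np.any(first_eligible >= len(pool)):
            raise ValueError("a target is longer than every pool sequence")
        for r in range(n_reps):
            tot = 0
            picks = first_eligible + (
                rng.random(n) * (len(pool) - first_eligible)
            ).astype(np.int64)
            for want, j in zip(target_lengths, picks):
                pi = int(order[j])
                have = int(pool.lengths[pi])
                if have == want:
                    tot += int(pool_counts[pi])
                else:
                    start = int(rng.integers(0, have - want + 1))
                    tot += _count_hits(
                        pool.sequences[pi][start : start + want], motif, threshold_frac
                    )
            null[r] = tot

    mu = float(np.median(null))
    sigma = float(np.std(null, ddof=1))
    if sigma == 0.0:
        return MotifNullResult(motif.id, observed, null, mu, sigma, None, None)
    z = (observed - mu) / sigma
    p = float(stats.norm.sf(z))
    return MotifNullResult(motif.id, observed, null, mu, sigma, float(z), p)
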