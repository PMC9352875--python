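"""Graph representativeness versus the number of construction samples.

A variant with true allele frequency f, observed in N diploid samples
(2N alleles, each carrying the alternate allele independently with
probability f), enters the graph when its observed frequency k/2N clears
the cut-off f_c. The observation count k is Binomial(2N, f), so

    P(added | f) = P(k >= ceil(2N * f_c))        (binomial survival)

Against an allele-frequency density p(f) over (0, 1], the expected rates
relative to the ideal graph (true AF >= f_c) are

    TPR = int_{f_c}^{1} P(added|f) p(f) df / int_{f_c}^{1} p(f) df
    FPR = int_{0}^{f_c} P(added|f) p(f) df / int_{f_c}^{1} p(f) df

Note the FPR denominator is the TRUE-variant mass, so FPR can exceed 1
for pathological densities. The empirical counterpart accrues samples one
by one from a genotyped population and scores each prefix-built graph
against the full-cohort (ideal) frequencies.

Threshold semantics: comparisons are ``>= f_c`` on both observed and
ideal AF; ties at exactly f_c are included. The binomial lower limit
``k >= 2N f_c`` is ``ceil`` with the exact-integer boundary included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from popgraph.popstats import MISSING, GenotypeMatrix

DEFAULT_GRID_BINS = 512


@dataclass(frozen=True)
class AFDensity:
    """Piecewise-constant allele-frequency density on (0, 1].

    ``edges`` are bin boundaries (len B+1, ascending, within [0, 1]);
    ``density`` the constant density value per bin, integrating to 1.
    """

    edges: tuple[float, ...]
    density: tuple[float, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        d = np.asarray(self.density, float)
        if e.ndim != 1 or len(e) != len(d) + 1:
            raise ValueError("edges must have len(density)+1 entries")
        if np.any(np.diff(e) <= 0) or e[0] < 0 or e[-1] > 1 + 1e-12:
            raise ValueError("edges must ascend within [0, 1]")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        total = float(np.sum(d * np.diff(e)))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density integrates to {total}, not 1")

    @classmethod
    def from_function(
        cls, fn, bins: int = DEFAULT_GRID_BINS, lo: float = 0.0, hi: float = 1.0
    ) -> "AFDensity":
        """Histogram approximation of an unnormalized density function."""
        edges = np.linspace(lo, hi, bins + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        d = np.asarray([max(0.0, float(fn(x))) for x in mid])
        d /= np.sum(d * np.diff(edges))
        return cls(tuple(edges), tuple(d))

    @classmethod
    def from_samples(cls, freqs, bins: int = DEFAULT_GRID_BINS) -> "AFDensity":
        """Empirical density from observed allele frequencies."""
        freqs = np.asarray(freqs, float)
        freqs = freqs[(freqs > 0) & (freqs <= 1)]
        if freqs.size == 0:
            raise ValueError("no frequencies in (0, 1]")
        hist, edges = np.histogram(freqs, bins=bins, range=(0.0, 1.0), density=True)
        return cls(tuple(edges), tuple(hist))

    @property
    def midpoints(self) -> np.ndarray:
        e = np.asarray(self.edges)
        return 0.5 * (e[:-1] + e[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges))

    def mass_above(self, cutoff: float) -> float:
        """Integral of the density over [cutoff, 1], midpoint classification."""
        mid, w = self.midpoints, self.widths
        return float(np.sum(np.where(mid >= cutoff, self.density, 0.0) * w))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n frequencies from the histogram density."""
        w = np.asarray(self.density) * self.widths
        p = w / w.sum()
        bins = rng.choice(len(p), size=n, p=p)
        e = np.asarray(self.edges)
        return rng.uniform(e[bins], e[bins + 1])

    def mean_heterozygosity(self) -> float:
        """E[2 f (1-f)] under the density: the per-locus diversity weight."""
        mid = self.midpoints
        return float(np.sum(2 * mid * (1 - mid) * self.density * self.widths))


@dataclass
class SelectionCurve:
    """Accrual TPR/FPR as a function of construction-sample count."""

    n_samples: list[int]
    tpr: list[float]
    fpr: list[float]
    af_cutoff: float

    def __post_init__(self) -> None:
        if not (len(self.n_samples) == len(self.tpr) == len(self.fpr)):
            raise ValueError("curve lists must align")
        if any(not (0.0 <= t <= 1.0) for t in self.tpr):
            raise ValueError("tpr out of [0,1]")


def _k_min(f_c: float, n_samples: int) -> int:
    """Smallest count k with k/2N >= f_c (exact boundary included)."""
    two_n = 2 * n_samples
    return math.ceil(two_n * f_c - 1e-12)


def prob_added(f: float, f_c: float, n_samples: int) -> float:
    """Probability a variant of true AF f clears the cut-off in N samples."""
    if not (0.0 < f_c <= 1.0):
        raise ValueError("f_c must be in (0, 1]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    k = _k_min(f_c, n_samples)
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, 2 * n_samples, f))


def _prob_added_grid(fs: np.ndarray, f_c: float, n_samples: int) -> np.ndarray:
    k = _k_min(f_c, n_samples)
    if k <= 0:
        return np.ones_like(fs)
    return stats.binom.sf(k - 1, 2 * n_samples, fs)


def theoretical_tpr(p: AFDensity, f_c: float, n_samples: int) -> float:
    """Expected fraction of truly common variants captured in N samples."""
    mid, w = p.midpoints, p.widths
    d = np.asarray(p.density)
    true_mass = p.mass_above(f_c)
    if true_mass <= 0:
        raise ValueError("density has no mass above the cut-off")
    add = _prob_added_grid(mid, f_c, n_samples)
    num = float(np.sum(np.where(mid >= f_c, add * d, 0.0) * w))
    return num / true_mass


def theoretical_fpr(p: AFDensity, f_c: float, n_samples: int) -> float:
    """Expected falsely-included variants relative to the ideal graph size."""
    mid, w = p.midpoints, p.widths
    d = np.asarray(p.density)
    true_mass = p.mass_above(f_c)
    if true_mass <= 0:
        raise ValueError("density has no mass above the cut-off")
    add = _prob_added_grid(mid, f_c, n_samples)
    num = float(np.sum(np.where(mid < f_c, add * d, 0.0) * w))
    return num / true_mass


def alt_dosage_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per sample x locus count of non-reference alleles, plus called-allele counts.

    Multi-allelic loci count any non-reference allele as alternate.
    """
    calls = gm.calls
    alt = ((calls != MISSING) & (calls > 0)).sum(axis=2)
    called = (calls != MISSING).sum(axis=2)
    return alt.astype(np.int64), called.astype(np.int64)


def ideal_af(gm: GenotypeMatrix) -> np.ndarray:
    """Full-cohort observed AF per locus — the truth standard for accrual."""
    alt, called = alt_dosage_matrix(gm)
    tot = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = alt.sum(axis=0) / tot
    return np.where(tot > 0, af, 0.0)


def sample_orderings(
    gm: GenotypeMatrix, strategy: str, seed: int
) -> np.ndarray:
    """An accrual order over sample indices.

    ``random``: seeded uniform shuffle. ``homogeneous``: round-robin
    across subpopulation strata in label order, shuffled within stratum
    (a stand-in for stratified cohort sampling).
    """
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    if strategy == "random":
        return rng.permutation(n)
    if strategy == "homogeneous":
        if gm.strata is None:
            raise ValueError("homogeneous ordering requires subpopulation labels")
        strata: dict[str, list[int]] = {}
        for i, label in enumerate(gm.strata):
            strata.setdefault(label, []).append(i)
        queues = []
        for label in sorted(strata):
            idx = np.asarray(strata[label])
            rng.shuffle(idx)
            queues.append(list(idx))
        order: list[int] = []
        while any(queues):
            for q in queues:
                if q:
                    order.append(q.pop(0))
        return np.asarray(order)
    raise ValueError(f"unknown strategy {strategy!r}")


def empirical_accrual(
    gm: GenotypeMatrix,
    order: np.ndarray | list[int],
    f_c: float,
    checkpoints: list[int] | None = None,
) -> SelectionCurve:
    """Score prefix-built graphs against full-cohort (ideal) frequencies.

    For each prefix of ``order``: observed AF from those samples; the graph
    holds variants with observed AF >= f_c; variants whose ideal AF >= f_c
    are true, the rest false. TPR and FPR are both normalized by the ideal
    graph size |{ideal AF >= f_c}|.
    """
    if not (0.0 < f_c < 1.0):
        raise ValueError("f_c must be in (0, 1)")
    order = np.asarray(order)
    if order.size < 1:
        raise ValueError("order must contain at least one sample")
    alt, called = alt_dosage_matrix(gm)
    alt_cum = np.cumsum(alt[order], axis=0)
    called_cum = np.cumsum(called[order], axis=0)
    ideal = ideal_af(gm)
    true_set = ideal >= f_c
    n_true = int(true_set.sum())
    if n_true == 0:
        raise ValueError("no variant clears the cut-off in the full cohort")
    ns = checkpoints if checkpoints is not None else list(range(1, order.size + 1))
    tpr, fpr = [], []
    for n in ns:
        if not (1 <= n <= order.size):
            raise ValueError(f"checkpoint {n} outside 1..{order.size}")
        with np.errstate(invalid="ignore", divide="ignore"):
            obs = np.where(
                called_cum[n - 1] > 0, alt_cum[n - 1] / called_cum[n - 1], 0.0
            )
        in_graph = obs >= f_c
        tp = int(np.sum(in_graph & true_set))
        fp = int(np.sum(in_graph & ~true_set))
        tpr.append(tp / n_true)
        fpr.append(fp / n_true)
    return SelectionCurve(n_samples=list(ns), tpr=tpr, fpr=fpr, af_cutoff=f_c)
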