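"""Random-matrix-theory threshold detection for similarity matrices.

The correlation threshold separating biological signal from noise is found
from the nearest-neighbour spacing distribution (NNSD) of the eigenvalues of
the thresholded similarity matrix.  Random matrix theory predicts two
universal limits for the NNSD of unfolded eigenvalues:

* Poisson statistics, P(d) = exp(-d), for uncorrelated eigenvalues, the
  signature of system-specific (modular) structure;
* Gaussian orthogonal ensemble (Wigner-Dyson) statistics,
  P(d) ~ (pi d / 2) exp(-pi d^2 / 4), for correlated eigenvalues, the
  signature of noise.

Scanning the threshold upwards, the NNSD undergoes a transition from GOE to
Poisson; the lowest threshold whose NNSD is consistent with the Poisson law
(chi-square goodness of fit, alpha = 0.01) is taken as the similarity cutoff
for network construction.  The scan is coarse (step 0.1 from 0.3) and then
fine (step 0.01 within the last coarse interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline

from .similarity import SimilarityMatrix

__all__ = [
    "ThresholdedMatrix",
    "NNSDResult",
    "ThresholdScanResult",
    "ScanStop",
    "NoTransitionError",
    "threshold_matrix",
    "unfold_eigenvalues",
    "nnsd_test",
    "detect_threshold",
]

#: eigenvalues closer than this are treated as degenerate and collapsed
DEGENERACY_TOL = 1e-8

#: unfolding spline knots at every KNOT_SPACING-th eigenvalue order statistic
KNOT_SPACING = 15


class ScanStop(RuntimeError):
    """The matrix at the current threshold is too small to yield spacing
    statistics; the scan must stop."""


class NoTransitionError(RuntimeError):
    """No threshold with Poisson NNSD was found before the scan ran out.

    Carries the scan trace in ``trace``.
    """

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class ThresholdedMatrix:
    """Weighted similarity matrix after zeroing entries below a threshold.

    Rows/columns whose off-diagonal entries all fall below the threshold are
    removed; the diagonal is kept at 1.
    """

    threshold: float
    otu_ids: list[str]
    values: np.ndarray

    @property
    def p(self) -> int:
        return len(self.otu_ids)


@dataclass
class NNSDResult:
    """Chi-square goodness-of-fit of unfolded spacings against exp(-d)."""

    eigenvalues: np.ndarray
    unfolded: np.ndarray
    spacings: np.ndarray
    chi2: float
    dof: int
    critical: float
    accepted_poisson: bool


@dataclass
class ScanRecord:
    threshold: float
    p: int
    chi2: float
    dof: int
    accepted: bool
    phase: str


@dataclass
class ThresholdScanResult:
    final_threshold: float
    trace: list[ScanRecord] = field(default_factory=list)

    def trace_rows(self) -> list[tuple]:
        return [
            (r.phase, r.threshold, r.p, r.chi2, r.dof, r.accepted) for r in self.trace
        ]


def threshold_matrix(S: SimilarityMatrix, s_tb: float) -> ThresholdedMatrix:
    """Zero all similarities below ``s_tb`` and drop empty rows/columns."""
    if not 0.0 <= s_tb <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    a = np.where(S.values >= s_tb, S.values, 0.0)
    np.fill_diagonal(a, 0.0)
    keep = np.flatnonzero((a > 0).any(axis=1))
    a = a[np.ix_(keep, keep)]
    np.fill_diagonal(a, 1.0)
    return ThresholdedMatrix(
        threshold=s_tb,
        otu_ids=[S.otu_ids[i] for i in keep],
        values=a,
    )


def _collapse_degenerate(eigs: np.ndarray, tol: float = DEGENERACY_TOL) -> np.ndarray:
    """Keep one representative of each cluster of near-equal eigenvalues.

    Exact ties produce artificial zero spacings that mimic Poisson
    clustering, so they are removed before unfolding.
    """
    eigs = np.sort(np.asarray(eigs, dtype=float))
    if eigs.size == 0:
        return eigs
    keep = [eigs[0]]
    for lam in eigs[1:]:
        if lam - keep[-1] >= tol:
            keep.append(lam)
    return np.array(keep)


def unfold_eigenvalues(
    eigenvalues: np.ndarray,
    method: str = "cubic_spline",
    min_eigs: int = 50,
    window: int = 11,
) -> np.ndarray:
    """Unfold an eigenvalue sequence and return nearest-neighbour spacings.

    Unfolding maps each eigenvalue through a smooth estimate of the
    integrated eigenvalue density so the mean local spacing becomes 1,
    isolating the fluctuation statistics from the global density.

    Parameters
    ----------
    method
        ``cubic_spline`` fits the cumulative eigenvalue count with a cubic
        least-squares spline (knots at every 10th order statistic);
        ``local_average`` divides each raw spacing by a moving average of
        the raw spacings.
    """
    lam = _collapse_degenerate(eigenvalues)
    n = lam.size
    if n < min_eigs:
        raise ScanStop(f"only {n} unique eigenvalues; need at least {min_eigs}")
    if method == "cubic_spline":
        counts = np.arange(1, n + 1, dtype=float)
        # knot spacing balances flexibility (follow the global density)
        # against over-fitting the staircase, which would distort the
        # spacing fluctuations the test relies on
        every = KNOT_SPACING
        knots = lam[every:-every:every]
        # Schoenberg-Whitney: knots must be strictly interior and increasing
        knots = knots[(knots > lam[0]) & (knots < lam[-1])]
        knots = np.unique(knots)
        if knots.size == 0:
            knots = np.array([lam[n // 2]])
        spline = LSQUnivariateSpline(lam, counts, t=knots, k=3)
        unfolded = spline(lam)
        spacings = np.diff(unfolded)
    elif method == "local_average":
        raw = np.diff(lam)
        half = window // 2
        padded = np.pad(raw, half, mode="edge")
        kernel = np.ones(window) / window
        local_mean = np.convolve(padded, kernel, mode="valid")
        spacings = raw / np.where(local_mean > 0, local_mean, np.inf)
        unfolded = np.concatenate([[0.0], np.cumsum(spacings)])
    else:
        raise ValueError(f"unknown unfolding method {method!r}")
    return np.clip(spacings, 0.0, None)


def nnsd_test(
    spacings: np.ndarray,
    alpha: float = 0.01,
    min_expected: float = 5.0,
) -> NNSDResult:
    """Chi-square goodness-of-fit of spacings against the Poisson law exp(-d).

    Spacings are histogrammed on [0, max(d)] with uniform bins; expected
    counts come from the unit-rate exponential (no fitted parameters after
    unfolding), the mass beyond max(d) is pooled into the rightmost bin, and
    bins are merged from the right until every expected count reaches
    ``min_expected``.  Degrees of freedom u = #bins - 1.
    """
    d = np.asarray(spacings, dtype=float)
    n = d.size
    if n < 30:
        raise ScanStop(f"only {n} spacings; need at least 30 for the chi-square test")
    dmax = float(d.max())
    if dmax <= 0:
        raise ScanStop("all spacings are zero")
    nbins = max(2, int(np.ceil(np.sqrt(n))))
    edges = np.linspace(0.0, dmax, nbins + 1)
    obs, _ = np.histogram(d, bins=edges)
    cdf = 1.0 - np.exp(-edges)
    expected = n * np.diff(cdf)
    expected[-1] += n * np.exp(-dmax)  # pool the right tail mass
    # merge bins from the right until every expected count is large enough
    # (the exponential's expected counts decay monotonically, so all
    # deficient bins form a right-tail suffix)
    obs_list = list(obs.astype(float))
    exp_list = list(expected)
    while len(exp_list) > 2 and min(exp_list) < min_expected:
        last_e, last_o = exp_list.pop(), obs_list.pop()
        exp_list[-1] += last_e
        obs_list[-1] += last_o
    if len(exp_list) < 2 or min(exp_list) <= 0:
        raise ScanStop("fewer than 2 usable histogram bins")
    obs_arr = np.array(obs_list)
    exp_arr = np.array(exp_list)
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    dof = len(exp_list) - 1
    critical = float(stats.chi2.ppf(1.0 - alpha, dof))
    unfolded = np.concatenate([[0.0], np.cumsum(d)])
    return NNSDResult(
        eigenvalues=np.array([]),
        unfolded=unfolded,
        spacings=d,
        chi2=chi2,
        dof=dof,
        critical=critical,
        accepted_poisson=bool(chi2 <= critical),
    )


def _test_threshold(
    S: SimilarityMatrix,
    t: float,
    alpha: float,
    min_matrix_size: int,
    method: str,
    phase: str,
) -> tuple[ScanRecord, ThresholdedMatrix]:
    tm = threshold_matrix(S, t)
    if tm.p < min_matrix_size:
        raise ScanStop(
            f"matrix shrank to {tm.p} OTUs (< {min_matrix_size}) at threshold {t:.2f}"
        )
    eigs = np.linalg.eigvalsh(tm.values)
    spacings = unfold_eigenvalues(eigs, method=method, min_eigs=min_matrix_size)
    res = nnsd_test(spacings, alpha=alpha)
    rec = ScanRecord(
        threshold=t, p=tm.p, chi2=res.chi2, dof=res.dof, accepted=res.accepted_poisson,
        phase=phase,
    )
    return rec, tm


def detect_threshold(
    S: SimilarityMatrix,
    start: float = 0.3,
    coarse_step: float = 0.1,
    fine_step: float = 0.01,
    alpha: float = 0.01,
    min_matrix_size: int = 50,
    unfolding: str = "cubic_spline",
    max_threshold: float = 0.99,
) -> ThresholdScanResult:
    """Scan thresholds for the GOE-to-Poisson NNSD transition.

    Coarse phase: ascend from ``start`` by ``coarse_step`` until the Poisson
    null is first accepted at some s_tb.  Fine phase: ascend over
    [s_tb - coarse_step, s_tb] by ``fine_step``; the smallest accepted fine
    threshold is the final similarity cutoff.
    """
    trace: list[ScanRecord] = []

    def fail(msg: str) -> NoTransitionError:
        return NoTransitionError(f"no RMT transition found: {msg}", trace)

    coarse_accept = None
    k = 0
    while True:
        t = round(start + k * coarse_step, 10)
        if t > max_threshold:
            raise fail(f"threshold exceeded {max_threshold} without Poisson acceptance")
        try:
            rec, _ = _test_threshold(S, t, alpha, min_matrix_size, unfolding, "coarse")
        except ScanStop as exc:
            raise fail(str(exc)) from exc
        trace.append(rec)
        if rec.accepted:
            coarse_accept = t
            break
        k += 1

    fine_start = max(round(coarse_accept - coarse_step, 10), 0.0)
    n_fine = int(round((coarse_accept - fine_start) / fine_step))
    for j in range(n_fine + 1):
        t = round(fine_start + j * fine_step, 10)
        try:
            rec, _ = _test_threshold(S, t, alpha, min_matrix_size, unfolding, "fine")
        except ScanStop:
            # a fine threshold below the accepted coarse one may retain too
            # few OTUs only in pathological cases; skip it
            continue
        trace.append(rec)
        if rec.accepted:
            return ThresholdScanResult(final_threshold=t, trace=trace)
    raise fail("no fine-scale threshold accepted (coarse acceptance not reproduced)")
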