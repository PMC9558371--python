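"""Free-energy estimation from nonequilibrium work samples.

A WT -> mutant alchemical transformation driven in finite time dissipates
work; the Crooks fluctuation theorem relates the forward and reverse work
distributions, ``P_f(W) / P_r(-W) = exp(beta (W - dG))``, so the equilibrium
free-energy difference is recoverable from the two sample sets.  Two
estimators are provided:

* :func:`bar_estimate` -- the Bennett acceptance ratio in its
  maximum-likelihood form, solved as a one-dimensional root problem; the
  statistically efficient choice.
* :func:`crooks_crossing_estimate` -- Gaussian fits to the forward and
  negated-reverse work samples, returning the crossing point of the fitted
  densities (which the fluctuation theorem places at W = dG).

Uncertainties come from an independent-direction bootstrap
(:func:`bootstrap_uncertainty`), and :func:`overlap_diagnostic` quantifies
forward/reverse distribution overlap, the regime in which both estimators
are reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

from .constants import beta_from_temperature

__all__ = [
    "WorkSet",
    "FreeEnergyEstimate",
    "EstimatorError",
    "NonOverlapError",
    "BootstrapFailureError",
    "bar_estimate",
    "crooks_crossing_estimate",
    "bootstrap_uncertainty",
    "overlap_diagnostic",
]

MethodTag = Literal["BAR", "crooks_crossing"]


class EstimatorError(RuntimeError):
    """An estimator could not produce a finite answer on this WorkSet."""


class NonOverlapError(EstimatorError):
    """Forward and reverse work distributions do not bracket a solution.

    Carries the histogram overlap coefficient as ``overlap`` so callers can
    report how disjoint the distributions were.
    """

    def __init__(self, message: str, overlap: float):
        super().__init__(f"{message} (overlap diagnostic = {overlap:.4f})")
        self.overlap = overlap


class BootstrapFailureError(EstimatorError):
    """More than half of the bootstrap replicates failed to estimate."""

    def __init__(self, n_failed: int, n_boot: int):
        super().__init__(
            f"estimator failed on {n_failed}/{n_boot} bootstrap replicates"
        )
        self.n_failed = n_failed
        self.n_boot = n_boot


@dataclass(frozen=True)
class WorkSet:
    """Paired forward/reverse work samples for one alchemical transformation.

    Parameters
    ----------
    forward_work, reverse_work
        Work values in kJ/mol for the WT->mutant (forward) and mutant->WT
        (reverse) driven transitions.  Both directions use the work actually
        performed along their own path, so at zero dissipation
        ``forward = dG`` and ``reverse = -dG``.
    temperature
        Simulation temperature in kelvin.
    transformation_id
        Free-form label, conventionally ``mutation_state_leg``.
    meta
        Optional provenance (e.g. the generating ``dg_true`` for synthetic
        sets); never consulted by the estimators.
    """

    forward_work: np.ndarray
    reverse_work: np.ndarray
    temperature: float
    transformation_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        fw = np.asarray(self.forward_work, dtype=float)
        rv = np.asarray(self.reverse_work, dtype=float)
        if fw.size == 0 or rv.size == 0:
            raise ValueError("both work directions must be non-empty")
        if not (np.all(np.isfinite(fw)) and np.all(np.isfinite(rv))):
            raise ValueError("work values must be finite")
        object.__setattr__(self, "forward_work", fw)
        object.__setattr__(self, "reverse_work", rv)
        beta_from_temperature(self.temperature)  # validates T > 0

    @property
    def beta(self) -> float:
        """1/(k_B*T) in mol/kJ."""
        return beta_from_temperature(self.temperature)

    @property
    def n_forward(self) -> int:
        return int(self.forward_work.size)

    @property
    def n_reverse(self) -> int:
        return int(self.reverse_work.size)

    def swapped(self) -> "WorkSet":
        """The time-reversed WorkSet (forward and reverse exchanged)."""
        return WorkSet(
            forward_work=self.reverse_work.copy(),
            reverse_work=self.forward_work.copy(),
            temperature=self.temperature,
            transformation_id=self.transformation_id,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A dG estimate in kJ/mol with its bootstrap standard error."""

    dg: float
    uncertainty: float
    method: MethodTag
    n_bootstrap: int = 0

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def _bar_objective(dg: float, ws: WorkSet) -> float:
    """Bennett maximum-likelihood self-consistency function.

    Monotone increasing in ``dg``; its root is the BAR estimate.  Uses the
    logistic form with the ln(n_f/n_r) offset so unequal sample counts are
    handled; with n_f = n_r the offset vanishes.
    """
    beta = ws.beta
    log_ratio = np.log(ws.n_forward / ws.n_reverse)
    fwd = expit(-(log_ratio + beta * (ws.forward_work - dg)))
    rev = expit(-(-log_ratio + beta * (ws.reverse_work + dg)))
    return float(np.sum(fwd) - np.sum(rev))


_BRACKET_PAD_KJ = 10.0  # bracket expansion beyond the pooled work range


def bar_estimate(
    ws: WorkSet,
    n_bootstrap: int = 0,
    seed: int | None = None,
    tol: float = 1e-10,
) -> FreeEnergyEstimate:
    """Bennett-acceptance-ratio maximum-likelihood estimate of dG.

    Solves the BAR self-consistency equation by bisection on the bracket
    ``[min(pooled work) - 10, max(pooled work) + 10]`` kJ/mol, to
    ``|f(dG)| < tol`` (or the bracket collapsing to machine width).

    With ``n_bootstrap > 0`` the returned uncertainty is the bootstrap
    standard error from :func:`bootstrap_uncertainty`; otherwise 0.

    Raises
    ------
    NonOverlapError
        If the objective has no sign change on the bracket, which happens
        when the two work distributions do not overlap.
    """
    pooled = np.concatenate([ws.forward_work, ws.reverse_work])
    lo = float(pooled.min()) - _BRACKET_PAD_KJ
    hi = float(pooled.max()) + _BRACKET_PAD_KJ
    f_lo = _bar_objective(lo, ws)
    f_hi = _bar_objective(hi, ws)
    if f_lo == 0.0:
        dg = lo
    elif f_hi == 0.0:
        dg = hi
    elif np.sign(f_lo) == np.sign(f_hi):
        raise NonOverlapError(
            "BAR objective has no sign change on the work bracket",
            overlap=overlap_diagnostic(ws),
        )
    else:
        # deterministic bisection; the objective is monotone increasing
        for _ in range(500):
            mid = 0.5 * (lo + hi)
            f_mid = _bar_objective(mid, ws)
            if abs(f_mid) < tol or (hi - lo) <= np.finfo(float).eps * max(
                1.0, abs(mid)
            ):
                break
            if np.sign(f_mid) == np.sign(f_lo):
                lo, f_lo = mid, f_mid
            else:
                hi = mid
        dg = 0.5 * (lo + hi) if abs(f_mid) >= tol else mid

    se = 0.0
    if n_bootstrap > 0:
        se = bootstrap_uncertainty(ws, "BAR", n_boot=n_bootstrap, seed=seed)
    return FreeEnergyEstimate(
        dg=float(dg), uncertainty=se, method="BAR", n_bootstrap=n_bootstrap
    )


def crooks_crossing_estimate(
    ws: WorkSet,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> FreeEnergyEstimate:
    """dG as the crossing of Gaussian fits to forward and negated-reverse work.

    The fluctuation theorem implies P_f(W) and P_r(-W) intersect exactly at
    W = dG, so the crossing of moment-fitted normal densities is a simple
    graphical estimator.  Equal fitted variances give the midpoint of the two
    means; otherwise the quadratic root lying between the means is returned.

    Raises
    ------
    EstimatorError
        On zero variance in either fit (unless both sample sets are a common
        point mass, whose shared mean is returned), or when neither quadratic
        root falls between the fitted means.
    """
    fwd = ws.forward_work
    neg_rev = -ws.reverse_work
    if fwd.size < 2 or neg_rev.size < 2:
        raise EstimatorError("need >= 2 samples per direction for a Gaussian fit")
    mu_f, s_f = float(np.mean(fwd)), float(np.std(fwd, ddof=1))
    mu_r, s_r = float(np.mean(neg_rev)), float(np.std(neg_rev, ddof=1))

    if s_f == 0.0 and s_r == 0.0 and mu_f == mu_r:
        dg = mu_f  # degenerate overlap: identical point masses
    elif s_f == 0.0 or s_r == 0.0:
        raise EstimatorError("zero variance in a fitted work distribution")
    elif abs(s_f - s_r) <= 1e-12 * max(s_f, s_r):
        dg = 0.5 * (mu_f + mu_r)
    else:
        # equate log-densities: quadratic a*x^2 + b*x + c = 0
        a = 1.0 / s_r**2 - 1.0 / s_f**2
        b = 2.0 * (mu_f / s_f**2 - mu_r / s_r**2)
        c = (mu_r**2 / s_r**2 - mu_f**2 / s_f**2) + 2.0 * np.log(s_r / s_f)
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise EstimatorError("fitted densities do not cross")
        roots = np.array(
            [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
        )
        lo, hi = sorted((mu_f, mu_r))
        pad = 1e-9 * (1.0 + hi - lo)
        between = roots[(roots >= lo - pad) & (roots <= hi + pad)]
        if between.size == 0:
            raise EstimatorError(
                "no density crossing between the fitted means "
                f"(means {mu_f:.3f}/{mu_r:.3f}, roots {roots})"
            )
        # if both roots land in the interval pick the one nearer its centre
        dg = float(between[np.argmin(np.abs(between - 0.5 * (lo + hi)))])

    se = 0.0
    if n_bootstrap > 0:
        se = bootstrap_uncertainty(
            ws, "crooks_crossing", n_boot=n_bootstrap, seed=seed
        )
    return FreeEnergyEstimate(
        dg=float(dg),
        uncertainty=se,
        method="crooks_crossing",
        n_bootstrap=n_bootstrap,
    )


_ESTIMATORS = {
    "BAR": bar_estimate,
    "crooks_crossing": crooks_crossing_estimate,
}


def bootstrap_uncertainty(
    ws: WorkSet,
    estimator: MethodTag = "BAR",
    n_boot: int = 100,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of a dG estimator on this WorkSet.

    Forward and reverse lists are resampled independently with replacement at
    their original sizes, the estimator is re-solved ``n_boot`` times, and
    the standard deviation of the replicate estimates is returned.
    Reproducible from ``seed``.

    Raises
    ------
    BootstrapFailureError
        If the estimator fails on more than half of the replicates.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    try:
        estimate = _ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(f"unknown estimator tag {estimator!r}") from None
    rng = np.random.default_rng(seed)
    replicates = []
    n_failed = 0
    for _ in range(n_boot):
        f_idx = rng.integers(0, ws.n_forward, size=ws.n_forward)
        r_idx = rng.integers(0, ws.n_reverse, size=ws.n_reverse)
        boot = WorkSet(
            forward_work=ws.forward_work[f_idx],
            reverse_work=ws.reverse_work[r_idx],
            temperature=ws.temperature,
            transformation_id=ws.transformation_id,
        )
        try:
            replicates.append(estimate(boot).dg)
        except EstimatorError:
            n_failed += 1
    if n_failed > n_boot // 2:
        raise BootstrapFailureError(n_failed, n_boot)
    return float(np.std(replicates, ddof=1))


def overlap_diagnostic(ws: WorkSet, n_bins: int | None = None) -> float:
    """Histogram overlap coefficient of forward vs negated-reverse work.

    Both sample sets are binned on a shared grid spanning their pooled range;
    the returned value is ``sum_i min(p_i, q_i)`` of the per-bin fractions:
    1 for identical distributions, 0 for disjoint ones.  Degenerate sets
    (all values equal) are treated as point masses.
    """
    fwd = ws.forward_work
    neg_rev = -ws.reverse_work
    lo = min(fwd.min(), neg_rev.min())
    hi = max(fwd.max(), neg_rev.max())
    if lo == hi:  # every value identical in both directions
        return 1.0
    if n_bins is None:
        # Rice rule on the pooled size; enough resolution without noise blowup
        n_bins = max(10, int(np.ceil(2.0 * (fwd.size + neg_rev.size) ** (1 / 3))))
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(fwd, bins=edges)
    q, _ = np.histogram(neg_rev, bins=edges)
    return float(
        np.minimum(p / fwd.size, q / neg_rev.size).sum()
    )
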