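"""Two-component Gaussian mixture thresholding of differential gene scores.

The distribution of knockout-subtracted gene scores is modelled as a
mixture of two normal components: a background component centred near zero
(genes whose enrichment does not depend on the depleted writer) and an
enriched component at positive scores (true targets). The mixture is fitted
by maximum likelihood via expectation-maximization on the raw values, the
components are labelled low/high by mean, and the target-calling threshold
is set at the low component's mean plus three of its standard deviations.
Genes whose differential score lies strictly above the threshold are called
positive.

Usage follows the model/results idiom::

    fit = TwoGaussianMixture(delta_values).fit(seed=0)
    print(fit.summary())
    calls = fit.call_targets(delta_by_gene, mark="H2AK119u1")
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "TwoGaussianMixture",
    "MixtureResults",
    "TargetCallSet",
    "InsufficientDataError",
    "DegenerateFitError",
]

MIN_VALUES = 50
SD_FLOOR = 1e-3
WEIGHT_FLOOR = 1e-4


class InsufficientDataError(ValueError):
    """Fewer finite values than the minimum required for a stable fit."""


class DegenerateFitError(RuntimeError):
    """Target calling refused because the mixture fit is degenerate."""


@dataclass
class MixtureResults:
    """Fitted two-Gaussian mixture and the derived calling threshold.

    ``threshold = mean_low + multiplier * sd_low`` (multiplier 3 by
    default). ``degenerate`` flags collapse of a component (weight below
    1e-4 or a standard deviation pinned at the floor) at convergence;
    degenerate fits refuse to call targets.
    """

    weight_low: float
    weight_high: float
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    multiplier: float
    log_likelihood: float
    loglik_trace: np.ndarray = field(repr=False)
    converged: bool
    degenerate: bool
    n_values: int
    n_iter: int
    n_restarts: int

    @property
    def threshold(self) -> float:
        return self.mean_low + self.multiplier * self.sd_low

    def pdf(self, x) -> np.ndarray:
        """Mixture density, useful for plotting over a score histogram."""
        x = np.asarray(x, dtype=float)
        return self.weight_low * norm.pdf(x, self.mean_low, self.sd_low) + (
            self.weight_high * norm.pdf(x, self.mean_high, self.sd_high)
        )

    def call_targets(
        self, delta: pd.Series, mark: str = "", allow_degenerate: bool = False
    ) -> "TargetCallSet":
        """Call genes with differential score strictly above the threshold.

        ``delta`` is indexed by gene id; missing values never call. Raises
        :class:`DegenerateFitError` on a degenerate or unconverged fit.
        ``allow_degenerate`` opts in to calling from a collapsed fit — the
        exact-arithmetic limit of noise-free scores, where both components
        are point masses at the floor sd yet the threshold is still
        meaningful.
        """
        if self.degenerate and not allow_degenerate:
            raise DegenerateFitError("refusing to call targets from a degenerate fit")
        if not self.converged:
            raise DegenerateFitError("refusing to call targets from an unconverged fit")
        values = pd.to_numeric(delta, errors="coerce")
        positive = values.index[values.to_numpy() > self.threshold]
        return TargetCallSet(
            mark=mark, positives=frozenset(positive), threshold=self.threshold
        )

    def summary(self) -> str:
        rows = [
            ("n values", f"{self.n_values}"),
            ("weight (low, high)", f"{self.weight_low:.4f}, {self.weight_high:.4f}"),
            ("mean (low, high)", f"{self.mean_low:.4f}, {self.mean_high:.4f}"),
            ("sd (low, high)", f"{self.sd_low:.4f}, {self.sd_high:.4f}"),
            ("threshold (mean_low + %.1f sd_low)" % self.multiplier, f"{self.threshold:.4f}"),
            ("log-likelihood", f"{self.log_likelihood:.4f}"),
            ("iterations / restarts", f"{self.n_iter} / {self.n_restarts}"),
            ("converged / degenerate", f"{self.converged} / {self.degenerate}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Two-Gaussian mixture fit", "=" * 40]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)


@dataclass(frozen=True)
class TargetCallSet:
    """Positive gene set for one mark at a stated threshold."""

    mark: str
    positives: frozenset
    threshold: float

    def __len__(self) -> int:
        return len(self.positives)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": sorted(self.positives),
                "mark": self.mark,
                "threshold": self.threshold,
            }
        )


def _em(values: np.ndarray, init: tuple, max_iter: int, tol: float):
    """One EM run from a given (w, m1, m2, s1, s2) start. Returns params + trace."""
    w, m1, m2, s1, s2 = init
    n = values.size
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities of the low component
        p1 = w * norm.pdf(values, m1, s1)
        p2 = (1.0 - w) * norm.pdf(values, m2, s2)
        total = p1 + p2
        total[total == 0.0] = np.finfo(float).tiny
        r1 = p1 / total
        ll = float(np.sum(np.log(total)))
        trace.append(ll)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break
        # M step
        n1 = r1.sum()
        n2 = n - n1
        w = n1 / n
        if n1 > 0:
            m1 = float(np.sum(r1 * values) / n1)
            s1 = float(np.sqrt(np.sum(r1 * (values - m1) ** 2) / n1))
        if n2 > 0:
            r2 = 1.0 - r1
            m2 = float(np.sum(r2 * values) / n2)
            s2 = float(np.sqrt(np.sum(r2 * (values - m2) ** 2) / n2))
        s1 = max(s1, SD_FLOOR)
        s2 = max(s2, SD_FLOOR)
    return w, m1, m2, s1, s2, np.asarray(trace), converged, it


class TwoGaussianMixture:
    """Maximum-likelihood two-Gaussian mixture model of a score sample.

    Parameters
    ----------
    values : array-like
        Differential (knockout-subtracted) gene scores, log2 units.
        Non-finite entries are dropped; at least 50 finite values are
        required.
    multiplier : float
        Threshold multiplier k in ``threshold = mean_low + k * sd_low``.

    Notes
    -----
    EM runs on the raw values (not a binned histogram). Initialization is
    deterministic: mean_low at the median, mean_high at the 95th
    percentile, both sds at half the overall sd, weights 0.9/0.1. On a
    degenerate outcome up to five restarts with jittered initials are
    attempted (seeded). Standard deviations are floored at 1e-3 score
    units; components are labelled low/high by mean, ties broken by
    smaller sd.
    """

    def __init__(self, values, multiplier: float = 3.0):
        arr = np.asarray(values, dtype=float).ravel()
        arr = arr[np.isfinite(arr)]
        if arr.size < MIN_VALUES:
            raise InsufficientDataError(
                f"need >= {MIN_VALUES} finite values, got {arr.size}"
            )
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        self.values = arr
        self.multiplier = float(multiplier)

    def _initial(self) -> tuple:
        v = self.values
        sd = float(np.std(v))
        return (
            0.9,
            float(np.median(v)),
            float(np.percentile(v, 95.0)),
            max(sd / 2.0, SD_FLOOR),
            max(sd / 2.0, SD_FLOOR),
        )

    def fit(
        self, max_iter: int = 500, tol: float = 1e-8, seed: int | None = 0
    ) -> MixtureResults:
        """Fit by EM; convergence at relative log-likelihood change < tol."""
        rng = np.random.default_rng(seed)
        init = self._initial()
        best = None
        restarts = 0
        for attempt in range(6):  # initial fit + up to 5 jittered restarts
            w, m1, m2, s1, s2, trace, converged, n_iter = _em(
                self.values, init, max_iter, tol
            )
            degenerate = (
                min(w, 1.0 - w) < WEIGHT_FLOOR or s1 <= SD_FLOOR or s2 <= SD_FLOOR
            )
            result = (w, m1, m2, s1, s2, trace, converged, n_iter, degenerate)
            if best is None or (not degenerate and best[-1]):
                best = result
            if not degenerate:
                break
            restarts = attempt + 1
            sd = float(np.std(self.values)) or 1.0
            base = self._initial()
            init = (
                float(np.clip(base[0] + rng.normal(0, 0.05), 0.05, 0.95)),
                base[1] + rng.normal(0, 0.25 * sd),
                base[2] + rng.normal(0, 0.25 * sd),
                max(base[3] * float(np.exp(rng.normal(0, 0.3))), SD_FLOOR),
                max(base[4] * float(np.exp(rng.normal(0, 0.3))), SD_FLOOR),
            )
        w, m1, m2, s1, s2, trace, converged, n_iter, degenerate = best
        # label components low/high by mean; ties by smaller sd
        if (m1, s1) <= (m2, s2):
            wl, ml, sl, wh, mh, sh = w, m1, s1, 1.0 - w, m2, s2
        else:
            wl, ml, sl, wh, mh, sh = 1.0 - w, m2, s2, w, m1, s1
        return MixtureResults(
            weight_low=wl,
            weight_high=wh,
            mean_low=ml,
            mean_high=mh,
            sd_low=sl,
            sd_high=sh,
            multiplier=self.multiplier,
            log_likelihood=float(trace[-1]),
            loglik_trace=trace,
            converged=converged,
            degenerate=degenerate,
            n_values=int(self.values.size),
            n_iter=n_iter,
            n_restarts=restarts,
        )
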