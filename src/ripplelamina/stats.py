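"""Bootstrap statistics shared by all analysis modules.

Two-condition comparisons throughout the pipeline use percentile bootstrap
tests on mean differences (paired or unpaired), and uncertainty on any scalar
statistic is reported as a percentile bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BootstrapResult:
    """Summary of a bootstrap mean-difference test.

    Attributes
    ----------
    observed : float
        Observed mean difference ``mean(x) - mean(y)``.
    mean : float
        Mean of the resampled difference distribution.
    ci_low, ci_high : float
        2.5th / 97.5th percentiles of the resampled differences.
    p : float
        Bootstrap p-value under the null of zero difference. Two-sided p is
        ``2 * min(tail fractions)`` capped at 1.
    n_resamples : int
    paired : bool
    sided : str
    seed : int | None
    """

    observed: float
    mean: float
    ci_low: float
    ci_high: float
    p: float
    n_resamples: int
    paired: bool
    sided: str
    seed: int | None


def bootstrap_test(
    x,
    y,
    *,
    paired: bool = False,
    sided: str = "two",
    n: int = 100_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Percentile bootstrap test of ``mean(x) - mean(y)`` against zero.

    For paired data, observation indices are resampled jointly so that the
    pairing is preserved; for unpaired data each condition is resampled
    independently. ``sided`` is one of ``"two"``, ``"greater"`` (x > y) or
    ``"less"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("bootstrap_test needs at least 2 observations per condition")
    if paired and x.size != y.size:
        raise ValueError("paired test requires equal-length samples")
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")

    rng = np.random.default_rng(seed)
    if paired:
        d = x - y
        idx = rng.integers(0, d.size, size=(n, d.size))
        diffs = d[idx].mean(axis=1)
    else:
        ix = rng.integers(0, x.size, size=(n, x.size))
        iy = rng.integers(0, y.size, size=(n, y.size))
        diffs = x[ix].mean(axis=1) - y[iy].mean(axis=1)

    frac_below = float(np.mean(diffs <= 0))
    frac_above = float(np.mean(diffs >= 0))
    if sided == "two":
        p = min(1.0, 2.0 * min(frac_below, frac_above))
    elif sided == "greater":
        p = frac_below
    else:
        p = frac_above
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(
        observed=float(x.mean() - y.mean()),
        mean=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(p),
        n_resamples=n,
        paired=paired,
        sided=sided,
        seed=seed,
    )


def bootstrap_ci(
    x,
    statistic=np.mean,
    *,
    n: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of ``statistic(x)``.

    Returns the (2.5th, 97.5th) percentiles of the statistic over ``n``
    resamples with replacement.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("bootstrap_ci needs non-empty data")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n, x.size))
    vals = np.apply_along_axis(statistic, 1, x[idx])
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
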