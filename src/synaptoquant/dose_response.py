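"""Dose-response fitting and population comparison.

Transfer versus surrogate-antigen density is modelled with the four-parameter
logistic ``y = bottom + (top - bottom) / (1 + (EC50/dose)^hill)``; ``top`` is
the fitted plateau (Tmax) and EC50 the density at half-maximal transfer.
Curves from different T-cell populations (or gene-edited cells) are compared
with the extra-sum-of-squares F test: the null model shares the parameter(s)
of interest across groups, the alternative fits them independently, and

    F = ((RSS_null - RSS_alt) / (df_null - df_alt)) / (RSS_alt / df_alt)

is referred to the F distribution.  Per-dose group contrasts use multiple
t tests with the step-down Holm-Šídák adjustment.  All fits are unweighted
least squares; dose 0 is evaluated as the lower asymptote rather than
dropped, so null-antigen conditions stay in the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .simulate import four_param_logistic

__all__ = [
    "DoseResponseFit",
    "CurveComparison",
    "fit_4pl",
    "compare_curves",
    "holm_sidak_adjust",
    "holm_sidak_multiple_t",
    "plot_fits",
]

_PARAM_NAMES = ("bottom", "top", "ec50", "hill")


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted logistic transfer curve."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    n: int
    parameterization: str          # "3pl" (bottom fixed at 0) or "4pl"
    converged: bool
    degenerate: bool = False       # EC50 unidentifiable (e.g. flat responses)

    @property
    def n_params(self) -> int:
        return 3 if self.parameterization == "3pl" else 4

    @property
    def df(self) -> int:
        return self.n - self.n_params

    def predict(self, dose) -> np.ndarray:
        return four_param_logistic(np.atleast_1d(dose), self.bottom, self.top,
                                   self.ec50, self.hill)


def _pack(bottom, top, ec50, hill, fix_bottom):
    p = [top, np.log(ec50), hill]
    return np.array(p if fix_bottom else [bottom] + p, dtype=float)


def _unpack(theta, fix_bottom):
    if fix_bottom:
        top, log_ec50, hill = theta
        bottom = 0.0
    else:
        bottom, top, log_ec50, hill = theta
    return bottom, top, float(np.exp(log_ec50)), hill


def _residuals(theta, doses, responses, fix_bottom):
    b, t, e, h = _unpack(theta, fix_bottom)
    return four_param_logistic(doses, b, t, e, h) - responses


def _starts(doses, responses):
    """Heuristic initial values plus log-spaced EC50 restarts."""
    lo, hi = float(np.min(responses)), float(np.max(responses))
    pos = doses[doses > 0]
    half = lo + 0.5 * (hi - lo)
    # dose where the response crosses half-range, log-interpolated
    order = np.argsort(doses)
    d_s, r_s = doses[order], responses[order]
    ec50_0 = None
    for i in range(len(d_s) - 1):
        r0, r1 = r_s[i], r_s[i + 1]
        if d_s[i + 1] > 0 and min(r0, r1) <= half <= max(r0, r1) and r1 != r0:
            f = (half - r0) / (r1 - r0)
            d0 = max(d_s[i], pos.min() / 2)
            ec50_0 = float(np.exp(np.log(d0) + f * (np.log(d_s[i + 1]) - np.log(d0))))
            break
    if not ec50_0 or not np.isfinite(ec50_0) or ec50_0 <= 0:
        ec50_0 = float(np.sqrt(pos.min() * pos.max()))
    ec50s = [ec50_0] + list(np.exp(np.linspace(np.log(pos.min()), np.log(pos.max()), 4)))
    return [(lo, hi, e, 1.0) for e in ec50s]


def fit_4pl(doses, responses, parameterization: str = "4pl") -> DoseResponseFit:
    """Least-squares logistic fit with multi-start initialization.

    ``parameterization`` is ``"4pl"`` (free bottom), ``"3pl"`` (bottom fixed
    at 0) or ``"auto"``, which picks between them by an extra-sum-of-squares
    F test of bottom = 0 at α = 0.05.  Flat response series are returned as
    degenerate fits (EC50 unidentifiable) rather than errors.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be matching 1-D arrays")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if not np.any(doses > 0):
        raise ValueError("need at least one positive dose")

    if parameterization == "auto":
        f3 = fit_4pl(doses, responses, "3pl")
        f4 = fit_4pl(doses, responses, "4pl")
        if f3.degenerate or f4.degenerate or f4.df <= 0:
            return f3
        num = max(f3.rss - f4.rss, 0.0) / (f3.df - f4.df)
        den = f4.rss / f4.df
        p = 1.0 if den == 0 else float(stats.f.sf(num / den, f3.df - f4.df, f4.df))
        return f3 if p >= 0.05 else f4
    if parameterization not in ("3pl", "4pl"):
        raise ValueError(f"unknown parameterization {parameterization!r}")
    fix_bottom = parameterization == "3pl"
    n_par = 3 if fix_bottom else 4
    if doses.size < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} points for a {parameterization} fit")

    if np.ptp(responses) == 0:  # flat: every EC50 fits equally well
        return DoseResponseFit(0.0 if fix_bottom else float(responses[0]),
                               float(responses[0]), float(np.median(doses[doses > 0])),
                               1.0, float(np.sum((responses - (0 if fix_bottom else responses[0])) ** 2)) if fix_bottom else 0.0,
                               doses.size, parameterization, converged=True, degenerate=True)

    best = None
    for (b, t, e, h) in _starts(doses, responses):
        theta0 = _pack(b, t, e, h, fix_bottom)
        try:
            sol = optimize.least_squares(
                _residuals, theta0, args=(doses, responses, fix_bottom),
                method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol)
    if best is None:
        raise RuntimeError(
            f"logistic fit failed to converge from any start "
            f"(n={doses.size}, range={np.ptp(responses):g})")
    rss, sol = best
    bottom, top, ec50, hill = _unpack(sol.x, fix_bottom)
    if hill < 0:  # flip to the increasing parameterization (symmetry of the 4PL)
        hill, bottom, top = -hill, top, bottom
    return DoseResponseFit(bottom, top, ec50, abs(hill), rss, doses.size,
                           parameterization, converged=bool(sol.success))


# ---------------------------------------------------------------------------
# extra-sum-of-squares comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveComparison:
    """Extra-sum-of-squares F test between grouped dose-response curves."""

    rss_null: float
    df_null: int
    rss_alt: float
    df_alt: int
    f_statistic: float
    p_value: float
    shared: tuple[str, ...]
    fits_alt: tuple[DoseResponseFit, ...]


def _shared_set(shared) -> tuple[str, ...]:
    aliases = {"ec50": ("ec50",), "tmax": ("top",), "top": ("top",),
               "both": ("ec50", "top"), "all": _PARAM_NAMES}
    if isinstance(shared, str):
        key = shared.lower()
        if key not in aliases:
            raise ValueError(f"unknown shared-parameter set {shared!r}")
        return aliases[key]
    out = []
    for s in shared:
        out.extend(_shared_set(s))
    return tuple(dict.fromkeys(out))


def compare_curves(groups, shared="all", parameterization: str = "4pl") -> CurveComparison:
    """Compare dose-response curves across groups by extra sum of squares.

    ``groups`` is a list of ``(doses, responses)`` pairs.  The alternative
    model fits every group independently; the null model constrains the
    ``shared`` parameter(s) (``"ec50"``, ``"tmax"``, ``"both"`` or ``"all"``)
    to a common value across groups.  Degrees of freedom follow the standard
    convention, n_total minus the number of fitted parameters.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    shared_names = _shared_set(shared)
    fix_bottom = parameterization == "3pl"
    per_group_names = [p for p in _PARAM_NAMES if p not in shared_names
                       and not (fix_bottom and p == "bottom")]
    shared_fit_names = [p for p in shared_names if not (fix_bottom and p == "bottom")]

    fits = [fit_4pl(d, r, parameterization) for d, r in groups]
    if not all(f.converged for f in fits):
        raise RuntimeError("a per-group fit failed to converge")
    rss_alt = sum(f.rss for f in fits)
    n_total = sum(f.n for f in fits)
    k = len(groups)
    df_alt = n_total - k * fits[0].n_params

    # null model: shared parameters common, others per group; EC50 fitted on log scale
    def transform(name, value, inverse=False):
        if name == "ec50":
            return np.exp(value) if inverse else np.log(value)
        return value

    def null_residuals(theta):
        res = []
        for (b, t, e, h), (d, r) in zip(split_theta(theta), groups):
            res.append(four_param_logistic(np.asarray(d, float), b, t, e, h)
                       - np.asarray(r, float))
        return np.concatenate(res)

    def split_theta(theta):
        common = {n: transform(n, v, inverse=True)
                  for n, v in zip(shared_fit_names, theta[:len(shared_fit_names)])}
        rest = theta[len(shared_fit_names):]
        out = []
        m = len(per_group_names)
        for g in range(k):
            own = {n: transform(n, v, inverse=True)
                   for n, v in zip(per_group_names, rest[g * m:(g + 1) * m])}
            p = {"bottom": 0.0, **common, **own}
            out.append((p["bottom"], p["top"], p["ec50"], p["hill"]))
        return out

    def start_vector():
        def avg(name):
            vals = [getattr(f, name) for f in fits]
            return float(np.exp(np.mean(np.log(vals)))) if name == "ec50" else float(np.mean(vals))
        theta = [transform(n, avg(n)) for n in shared_fit_names]
        for f in fits:
            theta.extend(transform(n, max(getattr(f, n), 1e-12) if n == "ec50"
                                   else getattr(f, n)) for n in per_group_names)
        return np.array(theta, dtype=float)

    sol = optimize.least_squares(null_residuals, start_vector(), method="lm",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10000)
    if not sol.success:
        raise RuntimeError("null (shared-parameter) model failed to converge")
    rss_null = float(np.sum(sol.fun ** 2))
    df_null = n_total - (len(shared_fit_names) + k * len(per_group_names))
    if rss_null < rss_alt:  # numerically the null can edge out stacked fits
        rss_null = rss_alt

    dfn = df_null - df_alt
    f_stat = ((rss_null - rss_alt) / dfn) / (rss_alt / df_alt) if rss_alt > 0 else np.inf
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, dfn, df_alt))
    return CurveComparison(rss_null, df_null, rss_alt, df_alt, f_stat, p,
                           shared_names, tuple(fits))


# ---------------------------------------------------------------------------
# Holm-Šídák multiple t tests
# ---------------------------------------------------------------------------


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Step-down Šídák adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    return multipletests(p, method="holm-sidak")[1]


def holm_sidak_multiple_t(group_pairs, alpha: float = 0.05,
                          paired: bool = True) -> pd.DataFrame:
    """Per-comparison two-tailed t tests with Holm-Šídák correction.

    ``group_pairs`` is a list of ``(a, b)`` measurement pairs, one per
    comparison (e.g. one per surrogate-antigen density).  Zero-variance
    comparisons get an exact-tie p (1 if the means agree, else 0) with a
    warning, since the t statistic is undefined there.
    """
    raw = []
    for i, (a, b) in enumerate(group_pairs):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if min(a.size, b.size) < 2:
            raise ValueError(f"comparison {i}: need at least two observations per side")
        if paired and a.size != b.size:
            raise ValueError(f"comparison {i}: paired sides must have equal size")
        degenerate = (np.std(a - b) == 0 if paired
                      else np.std(a) == 0 and np.std(b) == 0)
        if degenerate:
            warnings.warn(f"comparison {i} has zero variance; exact-tie p assigned",
                          stacklevel=2)
            raw.append(1.0 if np.mean(a) == np.mean(b) else 0.0)
            continue
        if paired:
            res = stats.ttest_rel(a, b)
        else:
            res = stats.ttest_ind(a, b)
        raw.append(float(res.pvalue))
    raw = np.asarray(raw)
    adjusted = holm_sidak_adjust(raw)
    return pd.DataFrame({
        "comparison": np.arange(len(raw)),
        "p_raw": raw,
        "p_adjusted": adjusted,
        "reject": adjusted < alpha,
    })


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------


def plot_fits(fits: dict[str, DoseResponseFit],
              data: dict[str, tuple[np.ndarray, np.ndarray]],
              path, ylabel: str = "transfer (cGMFI)") -> None:
    """Dose-response overlay: points per group plus fitted curves, log dose axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    all_pos = np.concatenate([np.asarray(d)[np.asarray(d) > 0] for d, _ in data.values()])
    grid = np.geomspace(all_pos.min() / 2, all_pos.max() * 1.2, 200)
    for name, (d, r) in data.items():
        pts = ax.plot(np.maximum(d, all_pos.min() / 2), r, "o", ms=4, label=name)
        fit = fits.get(name)
        if fit is not None:
            ax.plot(grid, fit.predict(grid), "-", color=pts[0].get_color(),
                    label=f"{name} fit (EC50={fit.ec50:.3g})")
    ax.set_xscale("log")
    ax.set_xlabel("surrogate antigen density (molec./µm²)")
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
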