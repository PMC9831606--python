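"""Concentration-response pharmacology: Hill fits and selectivity folds.

Inhibition of a channel subtype by a peptide is summarized by the Hill
equation with floor 0 and ceiling 1 (complete block at saturation):

    f([L]) = [L]^h / (IC50^h + [L]^h)

where f is the fraction of current inhibited, [L] the peptide
concentration (nM), IC50 the half-maximal inhibitory concentration and h
the Hill coefficient.  Fitting is nonlinear least squares in log(IC50)
space; in that parameterization the model is a logistic in log
concentration, which keeps the optimization well conditioned across many
decades.  95% confidence intervals come from a case-resampling bootstrap
by default, studentized (bootstrap-t) on log(IC50): at the dataset sizes
typical of these recordings (a few concentrations x a few cells) the
plain percentile interval measurably under-covers, while the studentized
interval is second-order accurate and attains nominal coverage (see
docs/methods.md).  Percentile and Wald intervals remain available for
cross-checking.

Subtype selectivity is expressed as fold = floor(IC50_subtype /
IC50_reference); floor (truncation toward zero) rather than rounding is
the convention reproduced throughout, and censored entries (">X") yield
censored fold lower bounds.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "hill",
    "DoseResponse",
    "InhibitionFraction",
    "fraction_inhibited",
    "HillFit",
    "fit_hill",
    "CensoredValue",
    "parse_ic50",
    "SelectivityMatrix",
    "selectivity_matrix",
    "rank_peptides",
]


def hill(concentration, ic50: float, h: float = 1.0, top: float = 1.0):
    """Fraction inhibited at ``concentration`` (same units as ``ic50``)."""
    c = np.asarray(concentration, dtype=float)
    return top * c**h / (ic50**h + c**h)


class InhibitionFraction(NamedTuple):
    fraction: float
    clipped: bool


def fraction_inhibited(i_drug: float, i_control: float) -> InhibitionFraction:
    """1 - i_drug/i_control, clipped to [0, 1] with a clip flag.

    Signs must share a convention (inward currents negative); current
    run-up can push the raw value outside [0, 1], which is clipped and
    flagged rather than propagated.
    """
    if i_control == 0:
        raise ValueError("control current is zero; fraction undefined")
    raw = 1.0 - i_drug / i_control
    clipped = not (0.0 <= raw <= 1.0)
    return InhibitionFraction(float(min(1.0, max(0.0, raw))), clipped)


@dataclass
class DoseResponse:
    """Per-cell concentration-response points for one peptide-subtype pair."""

    peptide: str
    subtype: str
    points: pd.DataFrame  # columns: concentration_nM, fraction_inhibited, cell_id

    def __post_init__(self) -> None:
        required = {"concentration_nM", "fraction_inhibited", "cell_id"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"dose-response table lacks columns {sorted(missing)}")
        if (self.points["concentration_nM"] <= 0).any():
            raise ValueError("concentrations must be positive")
        f = self.points["fraction_inhibited"]
        if ((f < 0) | (f > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.points["cell_id"].nunique()

    def to_csv(self, path: str | Path | None = None) -> str:
        df = self.points.copy()
        df.insert(0, "peptide", self.peptide)
        df.insert(1, "subtype", self.subtype)
        text = df.to_csv(index=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "list[DoseResponse]":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
            df = pd.read_csv(source)
        else:
            df = pd.read_csv(StringIO(str(source)))
        out = []
        for (pep, sub), grp in df.groupby(["peptide", "subtype"], sort=False):
            out.append(
                cls(
                    peptide=pep,
                    subtype=sub,
                    points=grp[["concentration_nM", "fraction_inhibited", "cell_id"]].reset_index(
                        drop=True
                    ),
                )
            )
        return out


@dataclass
class HillFit:
    """A fitted Hill curve with its confidence interval."""

    ic50: float  # nM
    hill_coefficient: float
    ci95: tuple[float, float]  # nM, on IC50
    n_cells: int
    ci_method: str
    converged: bool
    n_points: int
    residual_sd: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        lo, hi = self.ci95
        if not (lo <= self.ic50 <= hi):
            raise ValueError("CI must bracket the estimate")


def _initial_log_ic50(log_c: np.ndarray, y: np.ndarray) -> float:
    """Crossing of f = 0.5, interpolated on the concentration grid."""
    order = np.argsort(log_c)
    lc, yy = log_c[order], y[order]
    # average duplicate concentrations for the guess
    uniq, inv = np.unique(lc, return_inverse=True)
    means = np.array([yy[inv == i].mean() for i in range(len(uniq))])
    above = means >= 0.5
    if above.all():
        return float(uniq[0])
    if not above.any():
        return float(uniq[-1])
    i = int(np.argmax(above))
    if i == 0:
        return float(uniq[0])
    x0, x1, y0, y1 = uniq[i - 1], uniq[i], means[i - 1], means[i]
    if y1 == y0:
        return float(0.5 * (x0 + x1))
    return float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))


def _fit_single(
    log_c: np.ndarray, y: np.ndarray, fix_h: float | None
) -> tuple[float, float, bool, np.ndarray]:
    """Least-squares fit in (ln IC50, h); returns (ln_ic50, h, converged, jac)."""
    x0_logI = _initial_log_ic50(log_c, y)
    lo, hi = log_c.min() - 35.0, log_c.max() + 35.0

    if fix_h is None:

        def resid(theta):
            return 1.0 / (1.0 + np.exp(theta[1] * (theta[0] - log_c))) - y

        res = least_squares(
            resid, x0=[x0_logI, 1.0], bounds=([lo, 1e-3], [hi, 50.0]), xtol=1e-15,
            ftol=1e-15, gtol=1e-15,
        )
        return float(res.x[0]), float(res.x[1]), res.success, res.jac
    else:

        def resid(theta):
            return 1.0 / (1.0 + np.exp(fix_h * (theta[0] - log_c))) - y

        res = least_squares(resid, x0=[x0_logI], bounds=([lo], [hi]), xtol=1e-15,
                            ftol=1e-15, gtol=1e-15)
        return float(res.x[0]), float(fix_h), res.success, res.jac


def _fit_batch(
    log_c: np.ndarray,  # (B, n)
    y: np.ndarray,  # (B, n)
    theta0: np.ndarray,  # (2,) warm start from the full-data fit
    fix_h: float | None = None,
    n_iter: int = 60,
) -> np.ndarray:
    """Damped Gauss-Newton Hill fits for a batch of datasets at once.

    Used for the bootstrap, where thousands of small resampled fits would
    be prohibitively slow one at a time through a generic optimizer.  The
    model is a logistic in log concentration; each iteration solves the
    2x2 (or 1x1 with ``fix_h``) normal equations per dataset and applies
    per-dataset step halving until the cost does not increase.
    Returns (B, 2) [ln_ic50, h].
    """
    B = log_c.shape[0]
    theta = np.tile(np.asarray(theta0, dtype=float), (B, 1))
    lo_I, hi_I = log_c.min() - 35.0, log_c.max() + 35.0

    def cost(th):
        f = 1.0 / (1.0 + np.exp(th[:, [1]] * (th[:, [0]] - log_c)))
        r = f - y
        return (r**2).sum(axis=1), f, r

    c0, f, r = cost(theta)
    lam = 1e-10
    for _ in range(n_iter):
        w = f * (1.0 - f)  # df/d(logit argument)
        # d f / d lnI = -h w ; d f / d h = -(lnI - lnC) w
        j1 = -theta[:, [1]] * w
        if fix_h is None:
            j2 = -(theta[:, [0]] - log_c) * w
            a11 = (j1 * j1).sum(axis=1) + lam
            a12 = (j1 * j2).sum(axis=1)
            a22 = (j2 * j2).sum(axis=1) + lam
            g1 = (j1 * r).sum(axis=1)
            g2 = (j2 * r).sum(axis=1)
            det = a11 * a22 - a12 * a12
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            d1 = -(a22 * g1 - a12 * g2) / det
            d2 = -(-a12 * g1 + a11 * g2) / det
            step = np.stack([d1, d2], axis=1)
        else:
            a11 = (j1 * j1).sum(axis=1) + lam
            g1 = (j1 * r).sum(axis=1)
            step = np.stack([-g1 / a11, np.zeros(B)], axis=1)

        scale = np.ones(B)
        accepted = np.zeros(B, dtype=bool)
        for _half in range(12):
            cand = theta + scale[:, None] * step
            cand[:, 0] = np.clip(cand[:, 0], lo_I, hi_I)
            cand[:, 1] = np.clip(cand[:, 1], 1e-3, 50.0)
            c1, f1, r1 = cost(cand)
            better = (c1 <= c0 + 1e-15) & ~accepted
            theta[better] = cand[better]
            c0 = np.where(better, c1, c0)
            f[better] = f1[better]
            r[better] = r1[better]
            accepted |= better
            if accepted.all():
                break
            scale = np.where(accepted, scale, scale * 0.5)
    return theta


def _batch_se_ln_ic50(
    theta: np.ndarray, log_c: np.ndarray, y: np.ndarray, fix_h: float | None
) -> np.ndarray:
    """Linearized standard error of ln IC50 for each dataset in a batch."""
    f = 1.0 / (1.0 + np.exp(theta[:, [1]] * (theta[:, [0]] - log_c)))
    r = f - y
    w = f * (1.0 - f)
    j1 = -theta[:, [1]] * w
    n = y.shape[-1]
    if fix_h is None:
        j2 = -(theta[:, [0]] - log_c) * w
        a11 = (j1 * j1).sum(axis=1)
        a12 = (j1 * j2).sum(axis=1)
        a22 = (j2 * j2).sum(axis=1)
        det = a11 * a22 - a12 * a12
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        inv11 = a22 / det
        dof = max(n - 2, 1)
    else:
        a11 = (j1 * j1).sum(axis=1)
        inv11 = np.where(a11 < 1e-12, np.nan, 1.0 / a11)
        dof = max(n - 1, 1)
    s2 = (r**2).sum(axis=1) / dof
    return np.sqrt(np.clip(inv11 * s2, 0.0, None))


def fit_hill(
    dr: DoseResponse,
    fix_h: float | None = None,
    ci_method: str = "bootstrap",
    n_bootstrap: int = 2000,
    seed: int | None = None,
) -> HillFit:
    """Fit the Hill equation to a dose-response data set.

    Requires at least three distinct concentrations (two when ``fix_h``
    is given).  ``ci_method``:

    * ``"bootstrap"`` -- case-resampling bootstrap over data points
      (default B=2000), studentized on log IC50 (bootstrap-t);
    * ``"percentile"`` -- the same resamples, plain percentile interval;
    * ``"wald"`` -- normal interval on log IC50 from the fit's Jacobian.
    """
    c = dr.points["concentration_nM"].to_numpy(dtype=float)
    y = dr.points["fraction_inhibited"].to_numpy(dtype=float)
    n_distinct = len(np.unique(c))
    needed = 2 if fix_h is not None else 3
    if n_distinct < needed:
        raise ValueError(
            f"need >= {needed} distinct concentrations, got {n_distinct}"
        )
    if np.allclose(y, 0.0):
        raise ValueError("all responses are zero: no inhibition to fit")

    log_c = np.log(c)
    ln_ic50, h, ok, jac = _fit_single(log_c, y, fix_h)
    if not ok:
        raise RuntimeError(
            f"Hill fit did not converge (n={len(y)}, distinct conc={n_distinct})"
        )
    ic50 = math.exp(ln_ic50)
    resid = hill(c, ic50, h) - y
    dof = max(len(y) - (1 if fix_h is not None else 2), 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))

    if ci_method in ("bootstrap", "percentile"):
        rng = np.random.default_rng(seed)
        n = len(y)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        theta = _fit_batch(log_c[idx], y[idx], np.array([ln_ic50, h]), fix_h=fix_h)
        if ci_method == "percentile":
            lo, hi = np.exp(np.percentile(theta[:, 0], [2.5, 97.5]))
        else:
            theta0 = np.array([[ln_ic50, h]])
            se0 = float(
                _batch_se_ln_ic50(theta0, log_c[None, :], y[None, :], fix_h)[0]
            )
            se_b = _batch_se_ln_ic50(theta, log_c[idx], y[idx], fix_h)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (theta[:, 0] - ln_ic50) / se_b
            t = t[np.isfinite(t)]
            if len(t) < n_bootstrap // 2 or not np.isfinite(se0) or se0 == 0:
                # degenerate studentization; fall back to percentile
                lo, hi = np.exp(np.percentile(theta[:, 0], [2.5, 97.5]))
            else:
                q_lo, q_hi = np.percentile(t, [2.5, 97.5])
                lo = math.exp(ln_ic50 - q_hi * se0)
                hi = math.exp(ln_ic50 - q_lo * se0)
    elif ci_method == "wald":
        # covariance of (ln IC50[, h]) from the Jacobian at the optimum
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * residual_sd**2
            se = math.sqrt(max(cov[0, 0], 0.0))
        except np.linalg.LinAlgError:
            se = float("inf")
        lo, hi = math.exp(ln_ic50 - 1.96 * se), math.exp(ln_ic50 + 1.96 * se)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    lo = min(lo, ic50)
    hi = max(hi, ic50)
    return HillFit(
        ic50=ic50,
        hill_coefficient=h,
        ci95=(float(lo), float(hi)),
        n_cells=dr.n_cells,
        ci_method=ci_method,
        converged=True,
        n_points=len(y),
        residual_sd=residual_sd,
    )


# ---------------------------------------------------------------------------
# Selectivity

_CENSOR_RE = re.compile(r"^\s*>\s*([\d,.]+)\s*$")


@dataclass(frozen=True)
class CensoredValue:
    """A lower bound ">X" on an IC50 that was not reached experimentally."""

    bound: float

    def __str__(self) -> str:
        return f">{self.bound:g}"


def parse_ic50(value) -> float | CensoredValue:
    """Parse a numeric IC50 or a censored ``">X"`` entry (commas allowed)."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().replace(",", "")
    m = _CENSOR_RE.match(text)
    if m:
        return CensoredValue(float(m.group(1)))
    return float(text)


@dataclass
class SelectivityMatrix:
    """Fold selectivity of each subtype relative to a reference subtype."""

    reference: str
    table: pd.DataFrame  # columns: ic50_nM, censored, fold, fold_censored

    def to_csv(self, path: str | Path | None = None) -> str:
        df = self.table.copy()
        df["ic50_nM"] = [
            f">{v:g}" if c else f"{v:g}" for v, c in zip(df["ic50_nM"], df["censored"])
        ]
        df["fold"] = [
            f">{v}" if c else str(v) for v, c in zip(df["fold"], df["fold_censored"])
        ]
        text = df[["ic50_nM", "fold"]].to_csv(index_label="subtype")
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = ["| subtype | IC50 (nM) | fold vs " + self.reference + " |", "|---|---|---|"]
        for sub, row in self.table.iterrows():
            ic = f">{row.ic50_nM:g}" if row.censored else f"{row.ic50_nM:g}"
            fold = f">{row.fold}" if row.fold_censored else f"{row.fold}"
            lines.append(f"| {sub} | {ic} | {fold} |")
        return "\n".join(lines)


def selectivity_matrix(
    ic50s: Mapping[str, float | str | CensoredValue], reference: str
) -> SelectivityMatrix:
    """Fold selectivity fold = floor(IC50_subtype / IC50_reference).

    Censored subtype entries yield mechanical censored lower bounds
    ``> floor(bound / IC50_reference)``.  The reference must be present
    and uncensored; its fold is 1 by construction.
    """
    if reference not in ic50s:
        raise ValueError(f"reference subtype {reference!r} absent")
    parsed = {k: parse_ic50(v) for k, v in ic50s.items()}
    ref = parsed[reference]
    if isinstance(ref, CensoredValue):
        raise ValueError(f"reference subtype {reference!r} is censored")
    rows = []
    for subtype, value in parsed.items():
        if isinstance(value, CensoredValue):
            rows.append((subtype, value.bound, True, math.floor(value.bound / ref), True))
        else:
            rows.append((subtype, value, False, math.floor(value / ref), False))
    table = pd.DataFrame(
        rows, columns=["subtype", "ic50_nM", "censored", "fold", "fold_censored"]
    ).set_index("subtype")
    return SelectivityMatrix(reference=reference, table=table)


def _ordering_value(value) -> float:
    """Numeric ordering key: midpoint for ranges, bound for censored."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().replace(",", "")
    if text.startswith(">"):
        return float(text[1:])
    parts = re.split(r"[-–]", text)  # hyphen or en-dash range
    if len(parts) == 2 and all(p.strip() for p in parts):
        return (float(parts[0]) + float(parts[1])) / 2.0
    return float(text)


def rank_peptides(potencies: Mapping[str, float | str] | pd.DataFrame) -> pd.DataFrame:
    """Rank peptides by ascending IC50 (ranges ordered by midpoint).

    Ties preserve input order (stable sort).  Returns a DataFrame with
    columns ``ic50_nM`` (as given) and ``rank`` starting at 1.
    """
    if isinstance(potencies, pd.DataFrame):
        items = list(zip(potencies.iloc[:, 0], potencies.iloc[:, 1]))
    else:
        items = list(potencies.items())
    df = pd.DataFrame(items, columns=["peptide", "ic50_nM"])
    df["_key"] = df["ic50_nM"].map(_ordering_value)
    df = df.sort_values("_key", kind="stable").drop(columns="_key").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
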