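"""Quantification math for allele-specific silencing assays.

Covers the analysis path from raw qPCR cycle values to a selectivity call:

* ``2^-ΔΔCt`` relative expression fold-changes (target Ct normalized to a
  reference gene and to an untreated control);
* the relative-suppression screen (mutant knocked down by more than a
  threshold fraction *compared with* wild-type expression);
* four-parameter-logistic (4PL) dose-response fitting on log10
  concentration, reporting IC50 and fit quality;
* the selectivity index, IC50(wild-type) / IC50(mutant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit


def ddct_fold_change(
    treated: tuple[float, float], control: tuple[float, float]
) -> float:
    """Relative expression by the 2^-ΔΔCt method.

    Each argument is ``(Ct_target, Ct_reference)``; the result is
    ``2 ** -((ΔCt_treated) - (ΔCt_control))``.  Equal treated and control
    ΔCt give 1.0 by construction.
    """
    for ct in (*treated, *control):
        if not np.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    d_treated = treated[0] - treated[1]
    d_control = control[0] - control[1]
    return float(2.0 ** -(d_treated - d_control))


def screen_selective(
    mut_fold: float, wt_fold: float, threshold: float = 0.75
) -> tuple[bool, float]:
    """Relative-suppression screen on expression fold-changes.

    Passes when the mutant is suppressed by more than ``threshold`` compared
    with wild-type expression, i.e. ``mut_fold / wt_fold <= 1 - threshold``
    (default: mutant/wild-type ratio at or below 0.25).
    """
    if mut_fold <= 0 or wt_fold <= 0:
        raise ValueError("fold changes must be positive")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ratio = mut_fold / wt_fold
    return ratio <= (1.0 - threshold), float(ratio)


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------

def four_param_logistic(
    log10_dose: np.ndarray, top: float, bottom: float, log10_ic50: float, hill: float
) -> np.ndarray:
    """Decreasing 4PL response on log10 concentration; IC50 is the inflection."""
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (log10_dose - log10_ic50))
    )


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    r_squared: float
    n_points: int
    converged: bool
    flags: frozenset[str] = frozenset()

    @property
    def degenerate(self) -> bool:
        return "degenerate" in self.flags or "no_inhibition" in self.flags


#: 4PL fitting box: plateaus near the 0..1 fold-change scale, moderate slopes
FIT_BOUNDS = {
    "top": (0.5, 1.5),
    "bottom": (-0.2, 0.5),
    "hill": (0.2, 5.0),
}


def fit_dose_response(
    doses_nM: Sequence[float],
    responses: Sequence[float],
) -> DoseResponseFit:
    """Least-squares 4PL fit of response (expression fold-change) vs dose.

    Replicate observations (repeated doses) are summarized as mean ± SD per
    dose before fitting; when every dose has replicates the fit is weighted
    by the per-dose standard errors.  At least four distinct positive doses
    are required.  A fit whose plateaus collapse, or whose response rises with
    dose, is returned flagged rather than silently — the IC50 of a
    non-inhibitory curve is meaningless.
    """
    doses = np.asarray(doses_nM, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if doses.shape != resp.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    grouped = pd.DataFrame({"dose": doses, "resp": resp}).groupby("dose")["resp"]
    table = grouped.agg(["mean", "std", "count"])
    if len(table) < 4:
        raise ValueError(f"need >= 4 distinct doses, got {len(table)}")
    x = np.log10(table.index.to_numpy())
    y = table["mean"].to_numpy()
    # replicate scatter weights the fit (qPCR fold-change noise is strongly
    # heteroscedastic); single observations fall back to unweighted
    sem = table["std"].to_numpy() / np.sqrt(table["count"].to_numpy())
    use_weights = bool(np.all(table["count"].to_numpy() >= 2)) and np.all(
        np.isfinite(sem)
    )
    sigma = np.maximum(sem, 1e-3) if use_weights else None

    top0 = float(np.clip(y.max(), *FIT_BOUNDS["top"]))
    bottom0 = float(np.clip(y.min(), *FIT_BOUNDS["bottom"]))
    half = (top0 + bottom0) / 2.0
    log_ic50_0 = float(x[np.argmin(np.abs(y - half))])
    lo = [FIT_BOUNDS["top"][0], FIT_BOUNDS["bottom"][0], x.min() - 2.0,
          FIT_BOUNDS["hill"][0]]
    hi = [FIT_BOUNDS["top"][1], FIT_BOUNDS["bottom"][1], x.max() + 2.0,
          FIT_BOUNDS["hill"][1]]
    p0 = [top0, bottom0, float(np.clip(log_ic50_0, lo[2], hi[2])), 1.0]

    flags: set[str] = set()
    converged = True
    try:
        with warnings.catch_warnings():
            # degenerate plateaus make the covariance singular; the flags
            # below surface that more usefully than the warning
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                four_param_logistic,
                x,
                y,
                p0=p0,
                bounds=(lo, hi),
                sigma=sigma,
                absolute_sigma=sigma is not None,
                maxfev=20000,
            )
    except RuntimeError:
        converged = False
        popt = p0
        flags.add("no_convergence")
    top, bottom, log_ic50, hill = (float(v) for v in popt)

    y_hat = four_param_logistic(x, top, bottom, log_ic50, hill)
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if top - bottom < 0.1:
        flags.add("degenerate")
    if y[np.argmax(x)] > y[np.argmin(x)]:
        flags.add("no_inhibition")

    return DoseResponseFit(
        ic50=10.0**log_ic50,
        hill=hill,
        top=top,
        bottom=bottom,
        r_squared=r_squared,
        n_points=int(len(table)),
        converged=converged,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class SelectivityReport:
    ic50_mut: float
    ic50_wt: float
    selectivity_index: float
    flags: frozenset[str] = frozenset()

    @property
    def mutant_preferred(self) -> bool:
        return self.selectivity_index > 1.0


def selectivity_report(
    fit_mut: DoseResponseFit | float, fit_wt: DoseResponseFit | float
) -> SelectivityReport:
    """Selectivity index = IC50(wild-type) / IC50(mutant).

    Accepts fitted curves or bare IC50 values (nM); an index above 1 means
    the mutant allele is silenced at lower concentration.  Degenerate fits
    propagate as flags rather than being rejected.
    """
    flags: set[str] = set()
    if isinstance(fit_mut, DoseResponseFit):
        if fit_mut.degenerate:
            flags.add("degenerate_mut_fit")
        ic50_mut = fit_mut.ic50
    else:
        ic50_mut = float(fit_mut)
    if isinstance(fit_wt, DoseResponseFit):
        if fit_wt.degenerate:
            flags.add("degenerate_wt_fit")
        ic50_wt = fit_wt.ic50
    else:
        ic50_wt = float(fit_wt)
    if ic50_mut <= 0 or ic50_wt <= 0:
        raise ValueError("IC50 values must be positive")
    return SelectivityReport(
        ic50_mut=ic50_mut,
        ic50_wt=ic50_wt,
        selectivity_index=ic50_wt / ic50_mut,
        flags=frozenset(flags),
    )


# ---------------------------------------------------------------------------
# tabular input
# ---------------------------------------------------------------------------

DOSE_TABLE_COLUMNS = ("design", "allele", "dose_nM", "replicate", "fold_change")
CT_TABLE_COLUMNS = ("sample", "condition", "ct_target", "ct_reference")


def read_dose_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(DOSE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"dose table missing columns: {sorted(missing)}")
    return table


def fit_dose_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fit one 4PL curve per (design, allele) group of a dose table."""
    rows = []
    for (design, allele), grp in table.groupby(["design", "allele"]):
        fit = fit_dose_response(grp["dose_nM"], grp["fold_change"])
        rows.append(
            {
                "design": design,
                "allele": allele,
                "ic50_nM": fit.ic50,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "flags": ";".join(sorted(fit.flags)),
            }
        )
    return pd.DataFrame(rows)


def ddct_table(table: pd.DataFrame, control_condition: str = "untreated") -> pd.DataFrame:
    """Per-sample 2^-ΔΔCt fold-changes against the mean control ΔCt."""
    missing = set(CT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    controls = table[table["condition"] == control_condition]
    if controls.empty:
        raise ValueError(f"no rows with condition == {control_condition!r}")
    control_dct = float(
        (controls["ct_target"] - controls["ct_reference"]).mean()
    )
    out = table.copy()
    dct = out["ct_target"] - out["ct_reference"]
    out["fold_change"] = 2.0 ** -(dct - control_dct)
    return out
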