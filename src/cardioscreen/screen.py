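"""Primary-screen statistics: dilatation index, per-subset tests, hit selection.

The index of cardiac dilatation (ICD) is an affine rescaling of a treated
group's median diastolic diameter, anchored within each experiment subset so
that the untreated disease-model group scores 1 and healthy controls score 0:

    ICD = (median DD_treated - median DD_control)
          / (median DD_disease - median DD_control)

Treated vs untreated disease-model flies are compared per subset with a
two-sided Wilcoxon rank-sum (Mann-Whitney) test; at the end of the whole
screen a global Z-score pass over all per-subset ICDs catches compounds the
per-subset thresholds missed. A compound is selected when

    (ICD < icd_low or ICD > icd_high) and p < alpha,  or  |z| > z_cut,

with defaults icd_low=0.7, icd_high=1.3, alpha=0.05, z_cut=2. Suppressors
move the index toward 0 (protective), enhancers above 1 (aggravating).
P-values are deliberately uncorrected at this stage: confirmation is
deferred to the validation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synth import UNTREATED, LibraryManifest

__all__ = [
    "compute_icd",
    "subset_test",
    "global_zscores",
    "select_hits",
    "PrimaryScreen",
    "PrimaryScreenResults",
]

RESULT_COLUMNS = [
    "compound_id",
    "subset_id",
    "n_treated",
    "ICD",
    "p_wilcoxon",
    "z_score",
    "selected",
    "direction",
]


def compute_icd(
    dd_treated, dd_disease_untreated, dd_control
) -> float:
    """Index of cardiac dilatation from three diameter samples (µm).

    The unique affine index of group medians equal to 1 on the untreated
    disease-model group and 0 on controls. Invariant under any common
    rescaling or shift of all three samples.
    """
    t = np.asarray(dd_treated, dtype=float)
    d = np.asarray(dd_disease_untreated, dtype=float)
    c = np.asarray(dd_control, dtype=float)
    if t.size == 0 or d.size == 0 or c.size == 0:
        raise ValueError("all three samples must be non-empty")
    denom = np.median(d) - np.median(c)
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate subset: disease and control medians coincide"
        )
    return float((np.median(t) - np.median(c)) / denom)


def subset_test(dd_treated, dd_disease_untreated) -> float:
    """Two-sided Wilcoxon rank-sum P-value, treated vs untreated disease flies.

    Exact when sample sizes permit and there are no ties (scipy's automatic
    policy); normal approximation with tie correction otherwise. Fully tied
    samples give P = 1 with a warning.
    """
    t = np.asarray(dd_treated, dtype=float)
    d = np.asarray(dd_disease_untreated, dtype=float)
    if t.size < 2 or d.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if np.ptp(np.concatenate([t, d])) == 0:
        warnings.warn("all values tied across both samples; P = 1", stacklevel=2)
        return 1.0
    return float(stats.mannwhitneyu(t, d, alternative="two-sided").pvalue)


def global_zscores(results: pd.DataFrame) -> pd.DataFrame:
    """Z-score each compound's ICD against the full screen's ICD distribution.

    z = (ICD - mean) / sd over all finite ICDs, computed once at the end of
    the screen (population sd). Raises on a degenerate (zero-spread) screen.
    """
    icd = results["ICD"].to_numpy(dtype=float)
    finite = np.isfinite(icd)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite ICDs for Z-scores")
    sd = icd[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("all ICDs identical: Z-scores undefined")
    out = results.copy()
    out["z_score"] = (icd - icd[finite].mean()) / sd
    return out


def select_hits(
    results: pd.DataFrame,
    icd_low: float = 0.7,
    icd_high: float = 1.3,
    alpha: float = 5e-2,
    z_cut: float = 2.0,
    two_sided_z: bool = True,
) -> pd.DataFrame:
    """Flag selected compounds and their direction.

    Selection: (ICD outside [icd_low, icd_high] and p < alpha) or a global
    Z-score beyond ``z_cut`` (two-sided by default; set ``two_sided_z=False``
    to select only z > z_cut). Direction is suppressor for ICD < 1,
    enhancer otherwise; unselected compounds carry direction 'none'.
    """
    out = results.copy()
    icd = out["ICD"].to_numpy(dtype=float)
    p = out["p_wilcoxon"].to_numpy(dtype=float)
    z = out["z_score"].to_numpy(dtype=float)
    threshold_arm = ((icd < icd_low) | (icd > icd_high)) & (p < alpha)
    z_arm = (np.abs(z) > z_cut) if two_sided_z else (z > z_cut)
    selected = threshold_arm | z_arm
    out["selected"] = selected
    out["direction"] = np.where(
        selected, np.where(icd < 1.0, "suppressor", "enhancer"), "none"
    )
    return out


@dataclass
class PrimaryScreenResults:
    """Fitted primary-screen results.

    Attributes
    ----------
    results : DataFrame
        One row per evaluated compound: compound_id, subset_id, n_treated,
        ICD, p_wilcoxon, z_score, selected, direction.
    excluded : DataFrame
        Compounds never evaluated (toxic or without treated flies), with the
        exclusion reason. These never reach selection.
    subset_errors : dict
        subset_id -> message, for subsets skipped (e.g. missing anchors).
    """

    results: pd.DataFrame
    excluded: pd.DataFrame
    params: dict
    n_flies: int
    subset_errors: dict = field(default_factory=dict)

    @property
    def n_evaluated(self) -> int:
        return len(self.results)

    @property
    def suppressors(self) -> pd.DataFrame:
        return self.results[self.results["direction"] == "suppressor"]

    @property
    def enhancers(self) -> pd.DataFrame:
        return self.results[self.results["direction"] == "enhancer"]

    def summary(self) -> str:
        lines = [
            "Primary screen summary",
            "======================",
            f"flies analyzed:        {self.n_flies}",
            f"subsets:               {self.results['subset_id'].nunique()}",
            f"compounds evaluated:   {self.n_evaluated}",
            f"compounds excluded:    {len(self.excluded)}"
            + (
                f" ({', '.join(self.excluded['reason'].value_counts().index)})"
                if len(self.excluded)
                else ""
            ),
            f"selected suppressors:  {len(self.suppressors)}",
            f"selected enhancers:    {len(self.enhancers)}",
            "thresholds:            "
            f"ICD<{self.params['icd_low']} or >{self.params['icd_high']}, "
            f"p<{self.params['alpha']}, |z|>{self.params['z_cut']}",
        ]
        if self.subset_errors:
            lines.append("subset errors:")
            for sid, msg in self.subset_errors.items():
                lines.append(f"  {sid}: {msg}")
        return "\n".join(lines)


class PrimaryScreen:
    """Primary-screen model over a fly-record table.

    Parameters
    ----------
    flies : DataFrame
        Per-fly records with columns genotype ({control, disease}),
        treatment (compound id or 'untreated'), subset_id, and the diameter
        column (DD; EDD is used as fallback).
    manifest : LibraryManifest or DataFrame, optional
        Library manifest; compounds listed but lacking treated flies are
        reported as excluded (toxic compounds, by design, produce no flies).

    Call :meth:`fit` to run the per-subset index/test computation, the global
    Z-score pass and threshold selection.
    """

    def __init__(
        self,
        flies: pd.DataFrame,
        manifest: LibraryManifest | pd.DataFrame | None = None,
        metric: str = "DD",
    ):
        self.flies = pd.DataFrame(flies)
        if isinstance(manifest, pd.DataFrame):
            manifest = LibraryManifest(manifest)
        self.manifest = manifest
        if metric not in self.flies.columns:
            if "EDD" in self.flies.columns:
                metric = "EDD"
            else:
                raise ValueError(f"fly table lacks a {metric!r} (or EDD) column")
        self.metric = metric
        required = {"genotype", "treatment", "subset_id"}
        missing = required - set(self.flies.columns)
        if missing:
            raise ValueError(f"fly table missing columns: {sorted(missing)}")

    def fit(
        self,
        icd_low: float = 0.7,
        icd_high: float = 1.3,
        alpha: float = 5e-2,
        z_cut: float = 2.0,
        two_sided_z: bool = True,
    ) -> PrimaryScreenResults:
        flies = self.flies
        metric = self.metric
        rows = []
        subset_errors: dict[str, str] = {}
        for subset_id, sub in flies.groupby("subset_id", sort=True):
            disease = sub[(sub["genotype"] == "disease") & (sub["treatment"] == UNTREATED)]
            control = sub[(sub["genotype"] == "control") & (sub["treatment"] == UNTREATED)]
            if disease.empty or control.empty:
                subset_errors[str(subset_id)] = (
                    "missing anchor group(s): "
                    f"{disease.shape[0]} untreated disease, {control.shape[0]} control flies"
                )
                continue
            dd_d = disease[metric].to_numpy()
            dd_c = control[metric].to_numpy()
            treated = sub[(sub["genotype"] == "disease") & (sub["treatment"] != UNTREATED)]
            for compound_id, grp in treated.groupby("treatment", sort=True):
                dd_t = grp[metric].to_numpy()
                rows.append(
                    {
                        "compound_id": compound_id,
                        "subset_id": subset_id,
                        "n_treated": len(dd_t),
                        "ICD": compute_icd(dd_t, dd_d, dd_c),
                        "p_wilcoxon": subset_test(dd_t, dd_d),
                    }
                )
        results = pd.DataFrame(rows, columns=RESULT_COLUMNS[:5])
        if len(results):
            results = global_zscores(results)
            results = select_hits(
                results,
                icd_low=icd_low,
                icd_high=icd_high,
                alpha=alpha,
                z_cut=z_cut,
                two_sided_z=two_sided_z,
            )
        else:
            results["z_score"] = pd.Series(dtype=float)
            results["selected"] = pd.Series(dtype=bool)
            results["direction"] = pd.Series(dtype=object)

        excluded = self._excluded(results, subset_errors)
        params = dict(
            icd_low=icd_low, icd_high=icd_high, alpha=alpha, z_cut=z_cut,
            two_sided_z=two_sided_z, metric=self.metric,
        )
        return PrimaryScreenResults(
            results=results[RESULT_COLUMNS].reset_index(drop=True),
            excluded=excluded,
            params=params,
            n_flies=len(flies),
            subset_errors=subset_errors,
        )

    def _excluded(self, results: pd.DataFrame, subset_errors: dict) -> pd.DataFrame:
        if self.manifest is None:
            return pd.DataFrame(columns=["compound_id", "subset_id", "reason"])
        evaluated = set(results["compound_id"])
        rows = []
        for row in self.manifest.entries.itertuples(index=False):
            if row.compound_id in evaluated:
                continue
            if row.toxic_flag:
                reason = "toxic"
            elif str(row.subset_id) in subset_errors:
                reason = "subset_error"
            else:
                reason = "no_treated_flies"
            rows.append(
                {"compound_id": row.compound_id, "subset_id": row.subset_id, "reason": reason}
            )
        return pd.DataFrame(rows, columns=["compound_id", "subset_id", "reason"])
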