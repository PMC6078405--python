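"""Validation-stage statistics: normalization, IDD/ISD, nonparametric retention.

Validation experiments re-measure candidate compounds on larger samples with
the beat-resolved method (EDD/ESD per fly). Because independent experiments
drift slightly in absolute diameter scale, each experiment *i* is first
rescaled by a multiplicative coefficient

    N_i = grand median EDD(untreated disease, all experiments)
          / median EDD(untreated disease, experiment i),

anchored on the untreated disease-model group (the largest group, present in
every experiment). After pooling the normalized records, the indexes of
diastolic and systolic dilatation are

    IDD = (med EDD_treated - med EDD_control) / (med EDD_disease - med EDD_control)
    ISD = likewise with ESD,

equal to 1 on untreated disease-model flies and 0 on controls by
construction. Retention uses nonparametric ANOVA: a Kruskal-Wallis test over
the three groups with Dunn's post-hoc comparison (treated vs untreated
disease), retaining compounds with P below ``alpha`` (default 0.05). Dunn's
test is the pooled-rank z comparison with tie correction; its P-values are
reported per compound without further multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .screen import compute_icd
from .synth import UNTREATED

__all__ = [
    "ExperimentNormalization",
    "ValidationResult",
    "compute_normalizers",
    "apply_normalization",
    "compute_idd_isd",
    "dunn_test",
    "retention_test",
    "dose_response",
    "ValidationStudy",
    "ValidationResults",
]


@dataclass(frozen=True)
class ExperimentNormalization:
    """Multiplicative scale coefficient for one validation experiment."""

    experiment_id: str
    N_i: float
    anchor_median_dia: float  # µm, untreated-disease EDD median of the experiment

    def __post_init__(self) -> None:
        if self.N_i <= 0:
            raise ValueError("N_i must be positive")


@dataclass(frozen=True)
class ValidationResult:
    """Per-compound validation outcome."""

    compound_id: str
    IDD: float
    ISD: float
    p_kruskal: float
    p_kruskal_dunn: float
    retained: bool
    n_total: int


def compute_normalizers(records: pd.DataFrame) -> list[ExperimentNormalization]:
    """Per-experiment coefficients N_i aligning diameter scales before pooling.

    N_i = (grand median EDD of untreated disease flies over all experiments)
    / (that experiment's untreated-disease EDD median). A single experiment
    gets N = 1. Experiments lacking untreated disease flies are an error.
    """
    if "experiment_id" not in records.columns:
        records = records.assign(experiment_id="E1")
    anchors = records[
        (records["genotype"] == "disease") & (records["treatment"] == UNTREATED)
    ]
    missing = sorted(set(records["experiment_id"]) - set(anchors["experiment_id"]))
    if missing:
        raise ValueError(
            f"experiments lacking untreated disease anchor flies: {missing}"
        )
    grand = float(anchors["EDD"].median())
    out = []
    for exp_id, grp in anchors.groupby("experiment_id", sort=True):
        med = float(grp["EDD"].median())
        out.append(ExperimentNormalization(str(exp_id), grand / med, med))
    return out


def apply_normalization(
    records: pd.DataFrame, normalizers: list[ExperimentNormalization] | None = None
) -> pd.DataFrame:
    """Multiply each experiment's diameters (EDD, ESD, DD) by its N_i."""
    if "experiment_id" not in records.columns:
        records = records.assign(experiment_id="E1")
    if normalizers is None:
        normalizers = compute_normalizers(records)
    factor = records["experiment_id"].astype(str).map(
        {n.experiment_id: n.N_i for n in normalizers}
    )
    if factor.isna().any():
        bad = sorted(records.loc[factor.isna(), "experiment_id"].unique())
        raise ValueError(f"no normalizer for experiments {bad}")
    out = records.copy()
    for col in ("EDD", "ESD", "DD"):
        if col in out.columns:
            out[col] = out[col] * factor
    return out


def compute_idd_isd(
    treated: pd.DataFrame, disease: pd.DataFrame, control: pd.DataFrame
) -> tuple[float, float]:
    """Pooled diastolic and systolic dilatation indexes for one compound.

    Operates on (already normalized) record groups; uses group medians of
    EDD for IDD and ESD for ISD, with the same disease=1 / control=0
    anchoring as the primary-screen index.
    """
    for df, name in ((treated, "treated"), (disease, "disease"), (control, "control")):
        if len(df) == 0:
            raise ValueError(f"empty {name} group")
    idd = compute_icd(treated["EDD"], disease["EDD"], control["EDD"])
    isd = compute_icd(treated["ESD"], disease["ESD"], control["ESD"])
    return idd, isd


def dunn_test(groups: list[np.ndarray], i: int = 0, j: int = 1) -> float:
    """Dunn's post-hoc P-value for groups i vs j after a Kruskal-Wallis ranking.

    All observations are ranked jointly; the two groups' mean ranks are
    compared with a z statistic whose variance uses the pooled-rank formula
    with tie correction. Two-sided, unadjusted.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(arrays)
    n_total = all_vals.size
    ranks = stats.rankdata(all_vals)
    # tie correction: sum over tie groups of (t^3 - t)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    bounds = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [
        ranks[bounds[k] : bounds[k + 1]].mean() for k in range(len(arrays))
    ]
    ni, nj = arrays[i].size, arrays[j].size
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj)
    if var <= 0:
        return 1.0
    z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
    return float(2.0 * ndtr(-abs(z)))


def retention_test(
    treated,
    disease,
    control,
    alpha: float = 5e-2,
    compound_id: str = "",
    comparison: str = "treated_vs_disease",
    metric: str = "EDD",
) -> ValidationResult:
    """Kruskal-Wallis across the three groups with Dunn's post-hoc retention.

    ``treated``/``disease``/``control`` are 1D samples or record DataFrames
    (then ``metric`` selects the diameter column). The P-value of record is
    Dunn's treated-vs-untreated-disease comparison (or, with
    ``comparison="all_pairs"``, the minimum over all pairwise comparisons);
    the compound is retained when it falls below ``alpha``.
    """
    def _vals(x):
        if isinstance(x, pd.DataFrame):
            x = x[metric]
        return np.asarray(x, dtype=float)

    t, d, c = _vals(treated), _vals(disease), _vals(control)
    for arr, name in ((t, "treated"), (d, "disease"), (c, "control")):
        if arr.size < 2:
            raise ValueError(f"{name} group needs at least 2 flies")
    pooled = np.concatenate([t, d, c])
    if np.ptp(pooled) == 0:
        p_kw = 1.0
        p_dunn = 1.0
    else:
        p_kw = float(stats.kruskal(t, d, c).pvalue)
        if comparison == "treated_vs_disease":
            p_dunn = dunn_test([t, d, c], 0, 1)
        elif comparison == "all_pairs":
            p_dunn = min(
                dunn_test([t, d, c], a, b) for a, b in ((0, 1), (0, 2), (1, 2))
            )
        else:
            raise ValueError(f"unknown comparison {comparison!r}")
    return ValidationResult(
        compound_id=compound_id,
        IDD=np.nan,
        ISD=np.nan,
        p_kruskal=p_kw,
        p_kruskal_dunn=p_dunn,
        retained=bool(p_dunn < alpha),
        n_total=int(pooled.size),
    )


def dose_response(
    records: pd.DataFrame, dose_column: str = "concentration_um"
) -> tuple[pd.DataFrame, dict]:
    """Per-dose medians (with s.e.m.) of EDD/ESD/FS and a monotone-trend flag.

    Untreated flies enter as dose 0. The trend flag comes from the Spearman
    rank correlation between per-fly dose and ESD: a significant negative
    correlation marks a dose-dependent reduction of systolic dilatation.
    """
    recs = records.copy()
    recs[dose_column] = recs[dose_column].fillna(0.0)
    doses = np.sort(recs[dose_column].unique())
    if doses.size < 2:
        raise ValueError("dose-response requires at least 2 dose levels")
    rows = []
    for dose in doses:
        grp = recs[recs[dose_column] == dose]
        row = {"concentration_um": dose, "n": len(grp)}
        for col in ("EDD", "ESD", "FS"):
            if col in grp.columns:
                vals = grp[col].to_numpy(dtype=float)
                row[f"{col}_median"] = float(np.median(vals))
                row[f"{col}_sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        rows.append(row)
    summary = pd.DataFrame(rows)
    rho, p = stats.spearmanr(recs[dose_column], recs["ESD"])
    med = summary["ESD_median"].to_numpy()
    trend = {
        "spearman_rho": float(rho),
        "spearman_p": float(p),
        "decreasing_trend": bool(rho < 0 and p < 0.05),
        "strictly_decreasing_medians": bool(np.all(np.diff(med) < 0)),
    }
    return summary, trend


@dataclass
class ValidationResults:
    """Fitted validation-stage results: one row per compound."""

    results: pd.DataFrame  # compound_id, IDD, ISD, p_kruskal, p_kruskal_dunn, retained, n_total
    normalizers: list[ExperimentNormalization]
    params: dict
    n_flies: int

    @property
    def retained(self) -> pd.DataFrame:
        return self.results[self.results["retained"]]

    @property
    def suppressors(self) -> pd.DataFrame:
        r = self.retained
        return r[r["IDD"] < 1.0]

    @property
    def enhancers(self) -> pd.DataFrame:
        r = self.retained
        return r[r["IDD"] >= 1.0]

    def summary(self) -> str:
        lines = [
            "Validation summary",
            "==================",
            f"flies analyzed:       {self.n_flies}",
            f"experiments:          {len(self.normalizers)}",
            f"compounds tested:     {len(self.results)}",
            f"retained:             {len(self.retained)} "
            f"(alpha={self.params['alpha']})",
            f"  suppressors:        {len(self.suppressors)}",
            f"  enhancers:          {len(self.enhancers)}",
        ]
        return "\n".join(lines)


class ValidationStudy:
    """Validation-stage model over a fly-record table with EDD/ESD columns.

    Records may span several independent experiments (``experiment_id``
    column); diameters are rescaled per experiment before pooling. Each
    compound present in the table is scored (IDD, ISD, Kruskal-Wallis +
    Dunn) against the pooled untreated disease and control groups.
    """

    def __init__(self, flies: pd.DataFrame, compounds: list[str] | None = None):
        self.flies = pd.DataFrame(flies)
        required = {"genotype", "treatment", "EDD", "ESD"}
        missing = required - set(self.flies.columns)
        if missing:
            raise ValueError(f"fly table missing columns: {sorted(missing)}")
        self.compounds = compounds

    def fit(
        self,
        alpha: float = 5e-2,
        normalize: bool = True,
        comparison: str = "treated_vs_disease",
        metric: str = "EDD",
    ) -> ValidationResults:
        flies = self.flies
        normalizers = compute_normalizers(flies)
        if normalize:
            flies = apply_normalization(flies, normalizers)
        disease = flies[(flies["genotype"] == "disease") & (flies["treatment"] == UNTREATED)]
        control = flies[(flies["genotype"] == "control") & (flies["treatment"] == UNTREATED)]
        treated_all = flies[(flies["genotype"] == "disease") & (flies["treatment"] != UNTREATED)]
        compounds = self.compounds
        if compounds is None:
            compounds = sorted(treated_all["treatment"].unique())
        rows = []
        for cid in compounds:
            grp = treated_all[treated_all["treatment"] == cid]
            if grp.empty:
                continue
            idd, isd = compute_idd_isd(grp, disease, control)
            res = retention_test(
                grp, disease, control,
                alpha=alpha, compound_id=cid, comparison=comparison, metric=metric,
            )
            rows.append(
                {
                    "compound_id": cid,
                    "IDD": idd,
                    "ISD": isd,
                    "p_kruskal": res.p_kruskal,
                    "p_kruskal_dunn": res.p_kruskal_dunn,
                    "retained": res.retained,
                    "n_total": res.n_total,
                }
            )
        results = pd.DataFrame(
            rows,
            columns=[
                "compound_id", "IDD", "ISD", "p_kruskal",
                "p_kruskal_dunn", "retained", "n_total",
            ],
        )
        params = dict(alpha=alpha, normalize=normalize, comparison=comparison, metric=metric)
        return ValidationResults(
            results=results, normalizers=normalizers, params=params, n_flies=len(self.flies)
        )
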