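"""Pipeline orchestration over a workspace of movies and tables.

A workspace directory holds, per run:

* ``manifest.csv`` — the drug-library manifest;
* ``flies.csv`` — measured per-fly records, or
* ``movies/`` with per-fly TIFF stacks and a ``movies.csv`` sidecar mapping
  each file to its labels (genotype, treatment, subset_id, ...), in which
  case movies are measured first and a ``flies.csv`` is produced.

:func:`run_primary` writes ``results.csv`` (per-compound ICD, P, Z,
selection), ``excluded.csv`` and ``summary.txt``; :func:`run_validation`
writes ``validated.csv`` restricted to the primary-selected compounds. Every
input fly is accounted for exactly once: measured, excluded with a reason,
or failed with a reason (``measurement_log.csv``). All outputs are
deterministic under a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as csio
from .imaging import ImagingError, measure_movie
from .screen import PrimaryScreen, PrimaryScreenResults
from .synth import LibraryManifest
from .validate import ValidationResults, ValidationStudy

__all__ = ["ScreenConfig", "run_primary", "run_validation", "measure_workspace"]

CSV_FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds and imaging parameters of one screening run."""

    icd_low: float = 0.7
    icd_high: float = 1.3
    alpha: float = 5e-2
    z_cut: float = 2.0
    two_sided_z: bool = True
    retention_alpha: float = 5e-2
    threshold_fraction: float = 0.5
    smooth_sigma: float = 1.0
    line_position: int | None = None  # None = auto (max temporal variance row)
    projection: str = "percentile"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.icd_low < 1 < self.icd_high:
            raise ValueError("need 0 < icd_low < 1 < icd_high")
        if not 0 < self.alpha < 1 or not 0 < self.retention_alpha < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        cfg = cls(**csio.load_config(path))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        csio.save_config(path, asdict(self))


def measure_workspace(workspace: Path, config: ScreenConfig) -> pd.DataFrame:
    """Measure every movie in ``workspace/movies`` into a fly-record table.

    ``movies.csv`` must map each movie file to its labels. Unmeasurable
    flies (edge not found, trace rejected) are logged with their reason in
    ``measurement_log.csv`` and excluded from the table.
    """
    workspace = Path(workspace)
    sidecar = workspace / "movies.csv"
    if not sidecar.exists():
        raise FileNotFoundError(f"{sidecar} not found")
    mapping = pd.read_csv(sidecar)
    rows, log = [], []
    for rec in mapping.to_dict("records"):
        path = workspace / "movies" / str(rec["file"])
        try:
            movie = csio.read_movie(path)
            meas = measure_movie(
                movie,
                line_position=config.line_position,
                threshold_fraction=config.threshold_fraction,
                smooth_sigma=config.smooth_sigma,
                projection=config.projection,
            )
        except (ImagingError, FileNotFoundError, ValueError) as exc:
            log.append({**rec, "status": "failed", "reason": str(exc)})
            continue
        rows.append({**rec, **meas.as_dict()})
        log.append({**rec, "status": "measured", "reason": ""})
    pd.DataFrame(log).to_csv(
        workspace / "measurement_log.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    flies = pd.DataFrame(rows)
    flies.to_csv(workspace / "flies.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    return flies


def _load_flies(workspace: Path, config: ScreenConfig) -> pd.DataFrame:
    workspace = Path(workspace)
    flies_csv = workspace / "flies.csv"
    if flies_csv.exists():
        return pd.read_csv(flies_csv)
    if (workspace / "movies.csv").exists():
        return measure_workspace(workspace, config)
    raise FileNotFoundError(
        f"workspace {workspace} holds neither flies.csv nor movies.csv"
    )


def run_primary(
    workspace, config: ScreenConfig | None = None
) -> tuple[PrimaryScreenResults, str]:
    """Run the full primary screen over a workspace; write results and summary."""
    workspace = Path(workspace)
    config = config or ScreenConfig()
    config.validate()
    flies = _load_flies(workspace, config)
    manifest_csv = workspace / "manifest.csv"
    manifest = LibraryManifest.from_csv(manifest_csv) if manifest_csv.exists() else None
    model = PrimaryScreen(flies, manifest=manifest)
    res = model.fit(
        icd_low=config.icd_low,
        icd_high=config.icd_high,
        alpha=config.alpha,
        z_cut=config.z_cut,
        two_sided_z=config.two_sided_z,
    )
    res.results.to_csv(workspace / "results.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    res.excluded.to_csv(workspace / "excluded.csv", index=False)
    summary = res.summary()
    (workspace / "summary.txt").write_text(summary + "\n")
    return res, summary


def run_validation(
    workspace, config: ScreenConfig | None = None, flies: pd.DataFrame | None = None
) -> tuple[ValidationResults, str]:
    """Run validation statistics for the primary-selected compounds.

    Reads the primary ``results.csv`` for the selected set and
    ``validation_flies.csv`` (or, failing that, ``flies.csv``) for the
    validation measurements. An empty selected set yields an empty validated
    table without error.
    """
    workspace = Path(workspace)
    config = config or ScreenConfig()
    config.validate()
    results_csv = workspace / "results.csv"
    if not results_csv.exists():
        raise FileNotFoundError("primary results.csv not found; run the primary screen first")
    primary = pd.read_csv(results_csv)
    selected = sorted(primary.loc[primary["selected"], "compound_id"].astype(str))
    if flies is None:
        vpath = workspace / "validation_flies.csv"
        flies = pd.read_csv(vpath if vpath.exists() else workspace / "flies.csv")
    if selected:
        res = ValidationStudy(flies, compounds=selected).fit(alpha=config.retention_alpha)
    else:
        res = ValidationResults(
            results=pd.DataFrame(
                columns=[
                    "compound_id", "IDD", "ISD", "p_kruskal",
                    "p_kruskal_dunn", "retained", "n_total",
                ]
            ),
            normalizers=[],
            params=dict(alpha=config.retention_alpha),
            n_flies=len(flies),
        )
    res.results.to_csv(
        workspace / "validated.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    summary = res.summary() if len(res.results) else "Validation summary\n==================\nno selected compounds"
    (workspace / "validation_summary.txt").write_text(summary + "\n")
    return res, summary
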