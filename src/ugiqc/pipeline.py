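"""Stage orchestration: detect, classify, agree, and the report bundle.

Each ``run_*`` function is a pure file/DataFrame transformation used both by
the command-line interface and by the acceptance machinery. Reports carry
raw fractions alongside whole-percent renderings (half-up), and echo the
effective configuration for provenance. Compounds whose adduct m/z values
fall outside the acquisition window are excluded from every denominator.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .agreement import (
    confusion,
    pearson_auc,
    rate,
    stability_estimates,
)
from .chem_enum import DESCRIPTOR_NAMES, normalize_01
from .detection import (
    DetectionConfig,
    PeakList,
    call_detection,
    in_window,
    read_peaklists_csv,
    records_to_frame,
)
from .plate_io import heatmap_matrix, read_plate_csv, write_grid_csv
from .precip_model import (
    DescriptorVector,
    LabeledReaction,
    class_distributions,
    fit_outcome_model,
    label_frame,
    retained_count,
)

__all__ = [
    "DetectionSettings",
    "ReportSettings",
    "RunConfig",
    "run_agree",
    "run_classify",
    "run_detect",
    "run_report",
]


class DetectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tol_ppm: float = 10.0
    tol_da: float | None = None
    snr_min: float = 3.0
    mass_window: tuple[float, float] = (50.0, 650.0)

    def to_config(self) -> DetectionConfig:
        return DetectionConfig(
            tol_ppm=self.tol_ppm, tol_da=self.tol_da,
            snr_min=self.snr_min, mass_window=self.mass_window,
        )


class ReportSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rule: str = "any_adduct"        # compound-level aggregation rule
    reference_platform: str = "UPLC-MS"
    test_platform: str = "AEMS"
    model_seed: int = 0
    model_folds: int = 5


class RunConfig(BaseModel):
    """The one config file: unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    detection: DetectionSettings = DetectionSettings()
    report: ReportSettings = ReportSettings()
    simulation: dict = {}  # forwarded to SimulationConfig (validated there)


def _load_measured(campaign_dir: Path) -> pd.DataFrame:
    path = campaign_dir / "measured.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing upstream artifact: {path}")
    return pd.read_csv(path)


def run_detect(
    campaign_dir, config: DetectionConfig = DetectionConfig()
) -> pd.DataFrame:
    """Per-compound/platform/mode/adduct detection calls for a campaign dir.

    Expects ``reactions.csv`` (masses), ``measured.csv`` (which platform
    measured which compound in which well) and ``peaklists/*.csv``. Wells
    with no surviving signal may be absent from the peak-list files; they
    are treated as empty spectra. Adds an ``assessable`` column from the
    acquisition-window rule.
    """
    campaign_dir = Path(campaign_dir)
    reactions = pd.read_csv(campaign_dir / "reactions.csv")
    mass_of = dict(zip(reactions.product_id, reactions.monoisotopic_mass))
    measured = _load_measured(campaign_dir)

    by_key: dict[tuple[str, str, str], PeakList] = {}
    for path in sorted((campaign_dir / "peaklists").glob("*.csv")):
        for pl in read_peaklists_csv(path):
            by_key[(pl.platform, pl.mode, pl.well)] = pl

    modes = sorted({k[1] for k in by_key})
    records = []
    for row in measured.itertuples(index=False):
        mass = float(mass_of[row.compound_id])
        assessable = in_window(mass, config)
        for mode in modes:
            peaks = by_key.get(
                (row.platform, mode, row.well),
                PeakList(platform=row.platform, mode=mode, well=row.well),
            )
            if not assessable:
                continue
            records.extend(call_detection(row.compound_id, mass, peaks, config))
    frame = records_to_frame(records)
    assessable_ids = {
        cid for cid in measured.compound_id if in_window(float(mass_of[cid]), config)
    }
    frame["assessable"] = frame.compound_id.isin(assessable_ids)
    skipped = sorted(set(measured.compound_id) - assessable_ids)
    frame.attrs["not_assessable"] = skipped
    return frame


def _compound_flags(det: pd.DataFrame, platform: str, rule: str) -> dict[str, bool]:
    sub = det[det.platform == platform]
    agg = sub.groupby("compound_id")["detected"]
    return (agg.any() if rule == "any_adduct" else agg.all()).to_dict()


def _adduct_flags(det: pd.DataFrame, platform: str) -> dict[tuple, bool]:
    sub = det[det.platform == platform]
    return {
        (r.compound_id, r.adduct): bool(r.detected)
        for r in sub.itertuples(index=False)
    }


def run_agree(det: pd.DataFrame, settings: ReportSettings = ReportSettings()) -> dict:
    """Cross-platform agreement on the compounds measured by both platforms."""
    ref_p, test_p = settings.reference_platform, settings.test_platform
    common = sorted(
        set(det.loc[det.platform == ref_p, "compound_id"])
        & set(det.loc[det.platform == test_p, "compound_id"])
    )
    common_set = set(common)

    out: dict = {"n_common": len(common), "rule": settings.rule}
    ref_flags = {
        k: v for k, v in _compound_flags(det, ref_p, settings.rule).items()
        if k in common_set
    }
    test_flags = {
        k: v for k, v in _compound_flags(det, test_p, settings.rule).items()
        if k in common_set
    }
    cm = confusion(ref_flags, test_flags)
    out["confusion_compound"] = cm.as_dict()

    ref_add = {
        k: v for k, v in _adduct_flags(det, ref_p).items() if k[0] in common_set
    }
    test_add = {
        k: v for k, v in _adduct_flags(det, test_p).items() if k[0] in common_set
    }
    out["confusion_adduct"] = confusion(ref_add, test_add).as_dict()

    est = stability_estimates(ref_flags, test_flags)
    out["stability"] = {
        "n": est.n,
        "conservative": est.conservative,
        "permissive": est.permissive,
        "conservative_pct": est.conservative_pct,
        "permissive_pct": est.permissive_pct,
    }

    # AUC correlation per mode: [M+H]+ for positive, [M-H]- for negative;
    # compounds absent from every adduct on both platforms are stripped.
    any_ref = _compound_flags(det, ref_p, "any_adduct")
    any_test = _compound_flags(det, test_p, "any_adduct")
    out["correlation"] = {}
    for mode, adduct in (("positive", "[M+H]+"), ("negative", "[M-H]-")):
        auc = {}
        for platform in (ref_p, test_p):
            sub = det[
                (det.platform == platform) & (det.adduct == adduct)
                & det.compound_id.isin(common_set)
            ].set_index("compound_id")
            auc[platform] = sub["auc"].reindex(common).fillna(0.0).to_numpy()
        present = np.array([any_ref.get(c, False) or any_test.get(c, False)
                            for c in common])
        try:
            res = pearson_auc(auc[ref_p], auc[test_p], present)
            out["correlation"][mode] = {
                "r": res.r, "n_used": res.n_used, "n_excluded": res.n_excluded,
            }
        except ValueError as exc:
            out["correlation"][mode] = {"error": str(exc)}
    return out


def _reactions_to_labeled(reactions: pd.DataFrame) -> list[LabeledReaction]:
    out = []
    for r in reactions.itertuples(index=False):
        desc = DescriptorVector(
            slogp=float(r.slogp), topopsa=float(r.topopsa), smr=float(r.smr),
            mw=float(r.mw), nhbdon=int(r.nhbdon),
        )
        precip = bool(r.precipitated)
        purity = float(r.purity_pct) if precip else None
        out.append(LabeledReaction.build(r.product_id, desc, precip, purity))
    return out


def run_classify(
    reactions: pd.DataFrame, settings: ReportSettings = ReportSettings()
) -> dict:
    """Outcome labels, per-class descriptor summaries, feature importances."""
    labeled = _reactions_to_labeled(reactions)
    frac, pct = rate([r.precipitated for r in labeled])
    X = normalize_01(reactions[list(DESCRIPTOR_NAMES)])
    report = fit_outcome_model(
        X, reactions["precipitated"].to_numpy(dtype=bool),
        seed=settings.model_seed, n_folds=settings.model_folds,
    )
    return {
        "labels": label_frame(labeled),
        "class_distributions": class_distributions(labeled),
        "importance": report,
        "precipitation_rate": frac,
        "precipitation_rate_pct": pct,
        "retained_count": retained_count(labeled),
    }


def run_report(campaign_dir, outdir, config: RunConfig = RunConfig()) -> dict:
    """End-to-end report bundle for one campaign directory.

    Writes report.json plus per-compound truth-table, label, violin-summary
    and heatmap-grid CSVs into ``outdir``; returns the report dict.
    """
    campaign_dir, outdir = Path(campaign_dir), Path(outdir)
    for artifact in ("reactions.csv", "measured.csv", "peaklists"):
        if not (campaign_dir / artifact).exists():
            raise FileNotFoundError(
                f"missing upstream artifact: {campaign_dir / artifact}"
            )
    outdir.mkdir(parents=True, exist_ok=True)

    reactions = pd.read_csv(campaign_dir / "reactions.csv")
    det = run_detect(campaign_dir, config.detection.to_config())
    det.to_csv(outdir / "detections.csv", index=False)

    classify = run_classify(reactions, config.report)
    classify["labels"].to_csv(outdir / "labels.csv", index=False)
    classify["class_distributions"].to_csv(
        outdir / "descriptor_distributions.csv", index=False
    )

    agree = run_agree(det, config.report)
    truth = det.pivot_table(
        index="compound_id", columns=["platform", "mode", "adduct"],
        values="detected", aggfunc="first",
    )
    truth.columns = ["/".join(c) for c in truth.columns]
    truth.sort_index().to_csv(outdir / "truth_table.csv")

    per_platform = {}
    for platform in sorted(det.platform.unique()):
        flags = _compound_flags(det, platform, config.report.rule)
        frac, pct = rate(list(flags.values()))
        per_platform[platform] = {
            "n": len(flags), "detected": int(sum(flags.values())),
            "rate": frac, "rate_pct": pct,
        }

    # AEMS success heatmaps per 384-well plate
    grids = []
    test_flags = _compound_flags(det, config.report.test_platform, config.report.rule)
    for path in sorted((campaign_dir / "plates").glob("P384-*.csv")):
        for plate in read_plate_csv(path, plate_format=384):
            grid = heatmap_matrix(
                plate, {c: float(test_flags[c]) for c in plate.wells.values()
                        if c in test_flags},
            )
            gpath = outdir / f"heatmap_{plate.plate_id}.csv"
            write_grid_csv(grid, gpath, plate_format=384)
            grids.append(gpath.name)

    report = {
        "precipitation": {
            "n_reactions": int(len(reactions)),
            "n_precipitated": int(reactions.precipitated.sum()),
            "rate": classify["precipitation_rate"],
            "rate_pct": classify["precipitation_rate_pct"],
        },
        "retained_count": classify["retained_count"],
        "detection": per_platform,
        "agreement": agree,
        "feature_importance": classify["importance"].as_dict(),
        "not_assessable": det.attrs.get("not_assessable", []),
        "heatmaps": grids,
        "effective_config": config.model_dump(),
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report
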