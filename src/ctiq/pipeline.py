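"""End-to-end orchestration: simulate -> NPS / metrics -> dose -> compare.

``run_full`` drives the whole synthetic study at the published study
conditions (cohort sizes 16/12/23, four reconstructions with ASIR-V 50 as
baseline, phantom dose levels 1/3/5 mGy) and writes the report bundle:
a metric table and group summary (quantitative-analysis layout), an NPS
summary (phantom layout), a reader-score/kappa summary, percent-change
values, and a manifest.  Everything is deterministic given the seed.

``reproduce_published_changes`` recomputes the percent-change claims of the
published results text from the printed group means — pure arithmetic, no
simulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import published
from .dose import build_dose_records
from .io_formats import write_report
from .nps import compare_nps_by_dose, estimate_volume_nps
from .presets import (DOSE_LEVELS_MGY, NOISE_SUBJECT_CORRELATION, PROTOCOL_N,
                      PROTOCOL_REGION, PROTOCOL_TISSUES, RECON_PRESETS,
                      SCORE_AGREEMENT)
from .roi_metrics import build_metric_table, summarize_metrics
from .stats import (cohen_kappa, percent_change, rm_anova_bonferroni,
                    wilcoxon_signed_rank)
from .synthetic import (abdomen_layout, chest_layout, make_dose_series,
                        make_dose_table, make_patient_slice, make_scores)

log = logging.getLogger("ctiq.pipeline")


def _derive_seed(seed: int, *tags) -> int:
    """Stable, platform-independent sub-seed below 2^31."""
    digest = hashlib.sha256(f"{seed}:{':'.join(map(str, tags))}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    cohort_sizes: dict = field(default_factory=lambda: dict(PROTOCOL_N))
    reconstructions: tuple = tuple(published.RECONSTRUCTIONS)
    baseline: str = published.BASELINE
    dose_levels_mgy: tuple = DOSE_LEVELS_MGY
    out_dir: str = "results/run"
    phantom_size: tuple = (8, 256, 256)
    phantom_spacing: tuple = (2.5, 0.5, 0.5)
    patient_size_yx: tuple = (160, 160)
    patient_spacing: tuple = (2.5, 0.5, 0.5)
    #: optional reconstruction -> factor applied to the baseline cohort-mean
    #: noise instead of the preset means (e.g. {"DLR-H": 0.67})
    noise_scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline not in self.reconstructions:
            raise ValueError(f"baseline {self.baseline!r} not among reconstructions {self.reconstructions}")
        for proto, n in self.cohort_sizes.items():
            if n < 3:
                raise ValueError(f"protocol {proto!r}: n={n} < 3, too few subjects for paired statistics")
        unknown = [r for r in self.reconstructions if r not in RECON_PRESETS]
        if unknown:
            raise ValueError(f"no presets for reconstructions {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("reconstructions", "dose_levels_mgy", "phantom_size",
                    "phantom_spacing", "patient_size_yx", "patient_spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is excluded: the same study written elsewhere is the same study
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def simulate_phantom_nps(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phantom dose series per reconstruction -> NPS summary + dose-ratio tables."""
    rows, ratio_rows = [], []
    for recon in config.reconstructions:
        preset = RECON_PRESETS[recon]
        model = preset.noise_model(preset.phantom_sigma_1mgy,
                                   _derive_seed(config.seed, "phantom", recon))
        series = make_dose_series(config.phantom_size, config.phantom_spacing, 0.0,
                                  model, config.dose_levels_mgy, ref_dose_mgy=1.0)
        estimates = {}
        for dose, vol in series:
            est = estimate_volume_nps(vol)
            estimates[dose] = est
            rows.append({"reconstruction_id": recon, "dose_mgy": dose,
                         "nps_peak_hu2mm2": est.peak, "nps_f_avg_mm^-1": est.f_avg,
                         "n_rois": est.n_rois})
        comp = compare_nps_by_dose(estimates)
        for r in comp.pairs.itertuples(index=False):
            ratio_rows.append({"reconstruction_id": recon, **r._asdict(),
                               "f_avg_invariant": comp.f_avg_invariant})
    return pd.DataFrame(rows), pd.DataFrame(ratio_rows)


def _protocol_layout(protocol: str, size_yx, pixel_mm: float):
    tissues = PROTOCOL_TISSUES[protocol]
    if PROTOCOL_REGION[protocol] == "chest":
        return chest_layout(size_yx, pixel_mm, lung_hu=tissues["lung"], muscle_hu=tissues["muscle"])
    return abdomen_layout(size_yx, pixel_mm, liver_hu=tissues["liver"],
                          aorta_hu=tissues["aorta"], muscle_hu=tissues["muscle"])


def simulate_cohort_metrics(config: RunConfig, protocol: str) -> pd.DataFrame:
    """Per-subject metric rows for one protocol across all reconstructions.

    Subject-level noise is correlated across reconstructions (a large
    patient is noisy under every method), mimicking the paired design.
    """
    n = config.cohort_sizes[protocol]
    rho = NOISE_SUBJECT_CORRELATION
    rng = np.random.default_rng(_derive_seed(config.seed, "cohort", protocol))
    subject_effect = rng.standard_normal(n)
    base_mean = RECON_PRESETS[config.baseline].patient_noise[protocol][0]

    volumes, rois = {}, {}
    for i in range(n):
        subj = f"{protocol}_S{i:03d}"
        for recon in config.reconstructions:
            preset = RECON_PRESETS[recon]
            mean_sd = preset.patient_noise[protocol]
            mean = base_mean * config.noise_scale[recon] if recon in config.noise_scale else mean_sd[0]
            sd = mean_sd[1]
            eps = rng.standard_normal()
            sigma = max(2.0, mean + sd * (rho * subject_effect[i] + np.sqrt(1 - rho**2) * eps))
            layout = _protocol_layout(protocol, config.patient_size_yx, config.patient_spacing[-1])
            ps = make_patient_slice(
                layout, preset.noise_model(sigma, _derive_seed(config.seed, protocol, i, recon)),
                size_yx=config.patient_size_yx, spacing=config.patient_spacing)
            volumes[(subj, recon)] = ps.volume
            rois[subj] = ps.rois
    table = build_metric_table(volumes, rois)
    table.insert(0, "protocol", protocol)
    return table


def compare_metrics(metric_table: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Repeated-measures ANOVA + Bonferroni pairwise per protocol and metric."""
    rows = []
    for proto, grp in metric_table.groupby("protocol"):
        metric_cols = [c for c in grp.columns
                       if c.startswith(("attenuation_", "cnr_", "snr_")) or c == "noise"]
        for metric in metric_cols:
            if grp[metric].isna().all():
                continue  # metric not defined for this protocol's tissues
            wide = grp.pivot(index="subject_id", columns="reconstruction_id", values=metric)
            wide = wide[[c for c in grp["reconstruction_id"].unique()]]
            results = rm_anova_bonferroni(wide, baseline=baseline)
            for res in results:
                rows.append({"protocol": proto, "metric": metric, **asdict(res),
                             "df": str(res.df)})
    return pd.DataFrame(rows)


def simulate_scores_and_agreement(config: RunConfig) -> pd.DataFrame:
    """Reader scores per parameter and reconstruction: Wilcoxon vs baseline + kappa."""
    n_total = sum(config.cohort_sizes.values())
    rows = []
    for param, by_recon in published.TABLE3.items():
        scores = {}
        for recon in config.reconstructions:
            profile = np.array(by_recon[recon]["reviewer_1"], dtype=float)
            profile = np.round(profile / profile.sum() * n_total).astype(int)
            profile[np.argmax(profile)] += n_total - profile.sum()  # fix rounding drift
            scores[recon] = make_scores(n_total, profile, SCORE_AGREEMENT[param],
                                        _derive_seed(config.seed, "scores", param, recon))
        for recon in config.reconstructions:
            kap = cohen_kappa(scores[recon]["reviewer_1"], scores[recon]["reviewer_2"])
            if recon == config.baseline:
                wil_p, wil_stat = np.nan, np.nan
            else:
                wil = wilcoxon_signed_rank(scores[config.baseline]["reviewer_1"],
                                           scores[recon]["reviewer_1"])
                wil_p, wil_stat = wil.p_raw, wil.statistic
            rows.append({"parameter": param, "reconstruction_id": recon,
                         "kappa": kap.kappa, "kappa_band": kap.band,
                         "kappa_degenerate": kap.degenerate,
                         "wilcoxon_vs_baseline_stat": wil_stat,
                         "wilcoxon_vs_baseline_p": wil_p})
    return pd.DataFrame(rows)


def percent_changes_from_summary(summary: pd.DataFrame, baseline: str,
                                 target: str = "DLR-H") -> pd.DataFrame:
    """Percent change of group-mean noise/CNR/SNR, target vs baseline."""
    rows = []
    for proto, grp in summary.groupby("protocol"):
        for metric in grp["metric"].unique():
            if not (metric == "noise" or metric.startswith(("cnr_", "snr_"))):
                continue
            sel = grp[grp["metric"] == metric].set_index("reconstruction_id")["mean"]
            if baseline not in sel.index or target not in sel.index:
                continue
            if not (np.isfinite(sel[baseline]) and np.isfinite(sel[target])):
                continue  # metric not defined for this protocol's tissues
            direction = "reduction" if metric == "noise" else "increase"
            rows.append({"protocol": proto, "metric": metric, "direction": direction,
                         "baseline_mean": sel[baseline], "target_mean": sel[target],
                         "percent_change": percent_change(sel[baseline], sel[target], direction)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run


def run_full(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the tables in memory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
                "stages": {}}
    stage = "init"
    try:
        stage = "phantom_nps"
        log.info("stage %s", stage)
        nps_summary_df, nps_ratios = simulate_phantom_nps(config)
        bundle["nps_summary"] = nps_summary_df
        bundle["nps_dose_ratios"] = nps_ratios
        write_report(nps_summary_df, out / "nps_summary.csv")
        write_report(nps_ratios, out / "nps_dose_ratios.csv")
        manifest["stages"][stage] = {"outputs": ["nps_summary.csv", "nps_dose_ratios.csv"],
                                     "producer": "ctiq.nps.estimate_nps / compare_nps_by_dose"}

        stage = "cohort_metrics"
        log.info("stage %s", stage)
        tables = [simulate_cohort_metrics(config, proto) for proto in config.cohort_sizes]
        metric_table = pd.concat(tables, ignore_index=True)
        summary = (metric_table.groupby("protocol", group_keys=True)
                   .apply(summarize_metrics, include_groups=False).reset_index(level=0)
                   .reset_index(drop=True))
        bundle["metrics"] = metric_table
        bundle["metric_summary"] = summary
        write_report(metric_table, out / "metric_table.csv")
        write_report(summary, out / "metric_group_summary.csv")
        manifest["stages"][stage] = {"outputs": ["metric_table.csv", "metric_group_summary.csv"],
                                     "producer": "ctiq.roi_metrics.build_metric_table / summarize_metrics"}

        stage = "metric_statistics"
        log.info("stage %s", stage)
        stats_df = compare_metrics(metric_table, config.baseline)
        bundle["metric_stats"] = stats_df
        write_report(stats_df, out / "metric_stats.csv")
        manifest["stages"][stage] = {"outputs": ["metric_stats.csv"],
                                     "producer": "ctiq.stats.rm_anova_bonferroni"}

        stage = "percent_changes"
        pct = percent_changes_from_summary(summary, config.baseline)
        bundle["percent_changes"] = pct
        write_report(pct, out / "percent_changes.csv")
        manifest["stages"][stage] = {"outputs": ["percent_changes.csv"],
                                     "producer": "ctiq.stats.percent_change"}

        stage = "dose"
        log.info("stage %s", stage)
        dose_tables = []
        dose_params = {"chest": ((1.3, 0.5), (49.0, 26.3)),
                       "abdomen": ((1.5, 0.6), (77.9, 35.0))}  # cohort-reported means/SDs
        for proto in config.cohort_sizes:
            region = PROTOCOL_REGION[proto]
            ctdi, dlp = dose_params[region]
            dt = make_dose_table(config.cohort_sizes[proto], region,
                                 _derive_seed(config.seed, "dose", proto),
                                 ctdivol_mean_sd=ctdi, dlp_mean_sd=dlp)
            rec = build_dose_records(dt)
            rec.insert(0, "protocol", proto)
            dose_tables.append(rec)
        dose_df = pd.concat(dose_tables, ignore_index=True)
        bundle["dose"] = dose_df
        write_report(dose_df, out / "dose_records.csv")
        manifest["stages"][stage] = {"outputs": ["dose_records.csv"],
                                     "producer": "ctiq.dose.build_dose_records"}

        stage = "scores"
        log.info("stage %s", stage)
        scores_df = simulate_scores_and_agreement(config)
        bundle["scores"] = scores_df
        write_report(scores_df, out / "score_agreement.csv")
        manifest["stages"][stage] = {"outputs": ["score_agreement.csv"],
                                     "producer": "ctiq.stats.wilcoxon_signed_rank / cohen_kappa"}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# published-claim arithmetic (no simulation)


def reproduce_published_changes() -> pd.DataFrame:
    """Recompute every percent-change claim from the published group means.

    Each row: the claim, the value recomputed with
    :func:`ctiq.stats.percent_change` from the printed means, and the
    printed value.
    """
    rows = []
    for proto, metric, direction, printed in published.RESULTS_PERCENT_CLAIMS:
        base = published.TABLE1[proto][metric]["ASIR-V 50"][0]
        new = published.TABLE1[proto][metric]["DLR-H"][0]
        value = percent_change(base, new, direction)
        rows.append({"claim": f"{proto} {metric} {direction} (DLR-H vs ASIR-V 50)",
                     "computed_percent": value, "published_percent": printed,
                     "rounded_match": abs(round(value, 1) - printed) <= 0.05})
    proto, metric, direction, printed = published.RESULTS_CNR_VS_ASIRV100
    base = published.TABLE1[proto][metric]["ASIR-V 100"][0]
    new = published.TABLE1[proto][metric]["DLR-H"][0]
    value = percent_change(base, new, direction)
    rows.append({"claim": f"{proto} {metric} {direction} (DLR-H vs ASIR-V 100)",
                 "computed_percent": value, "published_percent": printed,
                 "rounded_match": abs(value - printed) <= 0.5})
    return pd.DataFrame(rows)


def published_nps_dose_decrease() -> float:
    """Mean percent of the 1 mGy NPS peak remaining at 5 mGy, over the four
    reconstructions, from the published phantom NPS table (reported ~21%)."""
    ratios = [published.TABLE2_NPS_PEAK[5][r] / published.TABLE2_NPS_PEAK[1][r]
              for r in published.RECONSTRUCTIONS]
    return 100.0 * float(np.mean(ratios))
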