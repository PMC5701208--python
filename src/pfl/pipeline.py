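"""Batch orchestration: samplesheet in, tables and review images out.

For every samplesheet row the pipeline loads the two channels and mask,
recognizes pore-free islands on the pan-NPC channel, computes QC flags,
detects counterstain foci inside accepted islands, measures sizes /
appearance frequencies / boundary-distance profiles, runs the per-island
CSR null, and finally aggregates per condition with Brunner-Munzel
comparisons.  Given identical inputs and seeds, every CSV output is
byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .foci import FociSet, detect_foci
from .io import Condition, QCReport, RawSample, RunConfig, compute_qc, load_sample
from .nullsim import SimulationSpec, simulate_island_null, simulated_island_profile
from .quantify import (
    DistanceProfile,
    aggregate_profiles,
    distance_field,
    distance_profile,
    island_metrics,
    split_proximal_distal,
)
from .segmentation import IslandSegmenter
from .stats import compare_conditions, compare_profiles

logger = logging.getLogger(__name__)

SAMPLESHEET_COLUMNS = [
    "sample_id",
    "channel_a_path",
    "channel_b_path",
    "mask_path",
    "inhibitor",
    "treatment_hours",
    "antibody",
    "pixel_size_um",
]


@dataclass
class SampleOutput:
    """Everything computed for one accepted sample."""

    sample: RawSample
    island_masks: list[np.ndarray]
    foci: FociSet
    records: list  # IslandRecord per island
    fields: list[np.ndarray]
    observed_profiles: list[DistanceProfile]
    simulated_counts: list[np.ndarray]
    simulated_profiles: list[DistanceProfile]
    island_seeds: list[int]


@dataclass
class PipelineResult:
    islands: pd.DataFrame
    profiles: pd.DataFrame
    stats: pd.DataFrame
    qc: pd.DataFrame
    outputs: list[SampleOutput] = field(default_factory=list)


def _condition_id(c: Condition) -> str:
    hours = (
        f"{c.treatment_hours:g}" if c.treatment_hours == c.treatment_hours else "na"
    )
    return f"{c.inhibitor}_{hours}h_{c.antibody}"


def process_sample(
    sample: RawSample, cfg: RunConfig, island_seed_start: int = 0
) -> tuple[SampleOutput | None, QCReport]:
    """Run segmentation, QC, detection, quantification and the CSR null
    for one sample.  Returns (None, qc) for rejected samples."""
    min_area_px = cfg.min_island_area / sample.pixel_size**2
    seg = IslandSegmenter(
        k_range=cfg.k_range,
        seed=cfg.kmeans_seed,
        restarts=cfg.kmeans_restarts,
        window=cfg.feature_window,
        min_island_area_px=min_area_px,
    ).fit(sample.channel_a, sample.nucleus_mask)
    qc = compute_qc(sample, seg.n_islands_pre_filter_, len(seg.island_masks_), cfg)
    if not qc.accepted:
        return None, qc

    foci = detect_foci(
        sample.channel_b,
        seg.island_masks_,
        sigma=cfg.curvature_sigma,
        min_area=cfg.min_focus_area,
        max_area=cfg.max_focus_area,
    )
    records, fields, obs, sim_counts, sim_profiles, seeds = [], [], [], [], [], []
    for i, mask in enumerate(seg.island_masks_):
        n_foci = foci.count_in_island(i)
        records.append(
            island_metrics(mask, n_foci, sample.pixel_size, sample.sample_id, i)
        )
        fld = distance_field(mask)
        fields.append(fld)
        coords = [f.centroid for f in foci.foci if f.island_id == i]
        obs.append(distance_profile(coords, fld, cfg.distance_bin))
        seed = cfg.sim_seed + island_seed_start + i
        seeds.append(seed)
        spec = SimulationSpec(mask, n_foci, cfg.sim_reps, seed)
        sim_counts.append(simulate_island_null(spec, fld, cfg.distance_bin))
        sim_profiles.append(simulated_island_profile(spec, fld, cfg.distance_bin))
    out = SampleOutput(
        sample, seg.island_masks_, foci, records, fields, obs, sim_counts,
        sim_profiles, seeds
    )
    return out, qc


def _write_sample_images(out: SampleOutput, out_dir: Path) -> None:
    """Label-mask TIFF (island ids as pixel values) and an overlay PNG."""
    label = np.zeros(out.sample.channel_a.shape, dtype=np.uint16)
    for i, m in enumerate(out.island_masks):
        label[m] = i + 1
    tifffile.imwrite(out_dir / f"{out.sample.sample_id}_islands.tif", label)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5), dpi=100)
    ax.imshow(out.sample.channel_a, cmap="gray", interpolation="nearest")
    for m in out.island_masks:
        ax.contour(m.astype(float), levels=[0.5], colors="red", linewidths=0.8)
    if out.foci.foci:
        rr = [f.centroid[0] for f in out.foci.foci]
        cc = [f.centroid[1] for f in out.foci.foci]
        ax.plot(cc, rr, "g+", markersize=5)
    ax.set_axis_off()
    fig.savefig(out_dir / f"{out.sample.sample_id}_overlay.png", bbox_inches="tight")
    plt.close(fig)


def _profile_rows(cond: str, profile: DistanceProfile, kind: str) -> list[dict]:
    rows = []
    norm = profile.normalized_frequency
    for b in range(profile.n_bins):
        rows.append(
            dict(
                condition=cond,
                kind=kind,
                bin_lo_px=float(profile.bin_edges[b]),
                bin_hi_px=float(profile.bin_edges[b + 1]),
                focus_count=float(profile.focus_counts[b]),
                pixel_count=int(profile.pixel_counts[b]),
                raw_frequency=float(profile.raw_frequency[b]),
                normalized_frequency=float(norm[b]) if norm is not None else np.nan,
                n_islands=profile.n_islands_aggregated,
            )
        )
    return rows


def run_pipeline(
    samplesheet: pd.DataFrame | str | Path,
    cfg: RunConfig,
    out_dir: str | Path | None = None,
    write_images: bool = True,
) -> PipelineResult:
    """Run the full per-cell pipeline and per-condition aggregation.

    ``samplesheet`` is a CSV path or DataFrame with columns
    ``sample_id, channel_a_path, channel_b_path, mask_path, inhibitor,
    treatment_hours, antibody, pixel_size_um``.  Individual sample
    failures are logged and flagged in QC without aborting the run.
    """
    if not isinstance(samplesheet, pd.DataFrame):
        samplesheet = pd.read_csv(samplesheet)
    if samplesheet.empty:
        raise ValueError("samplesheet is empty")
    missing = [c for c in SAMPLESHEET_COLUMNS if c not in samplesheet.columns]
    if missing:
        raise ValueError(f"samplesheet missing columns: {missing}")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_path / "run.log", mode="w")
        fh.setLevel(logging.INFO)
        logging.getLogger("pfl").addHandler(fh)
    try:
        return _run(samplesheet, cfg, out_path, write_images)
    finally:
        if out_path is not None:
            logging.getLogger("pfl").removeHandler(fh)
            fh.close()


def _run(
    sheet: pd.DataFrame, cfg: RunConfig, out_path: Path | None, write_images: bool
) -> PipelineResult:
    qc_rows: list[dict] = []
    island_rows: list[dict] = []
    outputs: list[SampleOutput] = []
    by_condition: dict[str, list[SampleOutput]] = {}
    island_counter = 0

    for row in sheet.itertuples(index=False):
        cond = Condition(str(row.inhibitor), float(row.treatment_hours), str(row.antibody))
        sid = str(row.sample_id)
        try:
            mask_path = row.mask_path if isinstance(row.mask_path, str) and row.mask_path else None
            sample = load_sample(
                row.channel_a_path, row.channel_b_path, mask_path, cond,
                float(row.pixel_size_um), sid,
            )
            out, qc = process_sample(sample, cfg, island_counter)
        except Exception as exc:  # per-sample failures must not abort the run
            logger.error("sample %s failed: %s", sid, exc)
            qc = QCReport(sid, flags={"ERROR"}, error=str(exc))
            out = None
        qc_rows.append(
            dict(
                sample_id=sid,
                condition=_condition_id(cond),
                saturation_fraction=qc.saturation_fraction,
                blur_metric=qc.blur_metric,
                n_islands_pre_filter=qc.n_islands_pre_filter,
                n_islands_post_filter=qc.n_islands_post_filter,
                flags=";".join(sorted(qc.flags)),
                accepted=qc.accepted,
                error=qc.error,
            )
        )
        if out is None:
            continue
        island_counter += len(out.island_masks)
        outputs.append(out)
        by_condition.setdefault(_condition_id(cond), []).append(out)
        for rec in out.records:
            island_rows.append(
                dict(
                    sample_id=rec.sample_id,
                    condition=_condition_id(cond),
                    inhibitor=cond.inhibitor,
                    treatment_hours=cond.treatment_hours,
                    antibody=cond.antibody,
                    island_id=rec.island_id,
                    area_px=rec.area_px,
                    area_um2=rec.area_um2,
                    n_foci=rec.n_foci,
                    frequency=rec.frequency,
                )
            )
        if write_images and out_path is not None:
            _write_sample_images(out, out_path)

    islands = pd.DataFrame(island_rows)
    qc_table = pd.DataFrame(qc_rows)

    profile_rows: list[dict] = []
    stat_rows: list[dict] = []
    for cond in sorted(by_condition):
        outs = by_condition[cond]
        obs_profiles = [p for o in outs for p in o.observed_profiles]
        sim_profiles = [p for o in outs for p in o.simulated_profiles]
        if not obs_profiles:
            continue
        obs_agg = aggregate_profiles(obs_profiles, kind="observed")
        sim_agg = aggregate_profiles(sim_profiles, kind="simulated")
        profile_rows += _profile_rows(cond, obs_agg, "observed")
        profile_rows += _profile_rows(cond, sim_agg, "simulated")
        prox, _dist = split_proximal_distal(obs_agg, cfg.proximal_fraction)
        obs_counts = [p.focus_counts for o in outs for p in o.observed_profiles]
        sim_counts = [c for o in outs for c in o.simulated_counts]
        try:
            region_tests = compare_profiles(obs_counts, sim_counts, len(prox))
        except ValueError as exc:
            logger.warning("profile comparison skipped for %s: %s", cond, exc)
            region_tests = {}
        for region, res in sorted(region_tests.items()):
            stat_rows.append(
                dict(
                    comparison_id=f"{cond}_profile_{region}",
                    measure=f"profile_{region}_share",
                    group_x="simulated",
                    group_y="observed",
                    n_x=res.n_x,
                    n_y=res.n_y,
                    statistic=res.statistic,
                    df=res.df,
                    p_value=res.p_value,
                    p_hat=res.p_hat,
                    label=res.significance_label,
                    sim_seed=cfg.sim_seed,
                )
            )

    if not islands.empty:
        for measure in ("area_um2", "frequency"):
            try:
                table = compare_conditions(islands, measure)
            except ValueError:
                continue
            for r in table.to_dict("records"):
                r = dict(r)
                r["comparison_id"] = (
                    f"{r['antibody']}_{r['treatment_hours']:g}h_{measure}_"
                    f"{r['group_x']}_vs_{r['group_y']}"
                )
                r["sim_seed"] = cfg.sim_seed
                stat_rows.append(r)

    profiles = pd.DataFrame(profile_rows)
    stats_table = pd.DataFrame(stat_rows)

    if out_path is not None:
        islands.to_csv(out_path / "islands.csv", index=False)
        profiles.to_csv(out_path / "profiles.csv", index=False)
        stats_table.to_csv(out_path / "stats.csv", index=False)
        qc_table.to_csv(out_path / "qc.csv", index=False)
    return PipelineResult(islands, profiles, stats_table, qc_table, outputs)
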