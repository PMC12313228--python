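"""End-to-end orchestration: simulate -> quantify -> score -> associate.

Each ``run_*`` function is a pure function of (inputs, config, seed), writes
CSV/TIFF/JSON outputs under ``config.output_dir`` and a provenance log
echoing every threshold used.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import grading, imagequant, stats, synthdata
from .config import RunConfig
from .io import ProvenanceLog, read_organ_image, read_sidecar, write_organ_image

__all__ = ["run_simulate", "run_quantify", "run_score", "run_associate", "run_all"]

#: Latent p-EMT gradient of the default six-population synthetic cohort.
PAPER_LIKE_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(
    config: RunConfig,
    n_experiments: int = 2,
    noise_sd: float = 0.0,
    ct_noise_sd_cycles: float = 0.2,
) -> dict:
    """Write a full synthetic dataset: images+sidecars, Ct table, densitometry,
    TF matrix, cell masks.  Deterministic per config.seed.

    The default cohort mirrors the study design: six keratinocyte populations
    on a latent p-EMT gradient, four TGF-β responders (2–4-fold pSMAD3
    stimulation) and two non-responders, nine image fields per experiment,
    50 cells per population for LWR, and 40 transcription factors of which
    one is coupled to the latent gradient.
    """
    out = _outdir(config)
    log = ProvenanceLog(config.asdict())
    rng = np.random.default_rng(config.seed)
    images_dir = out / "images"
    images_dir.mkdir(exist_ok=True)

    for e in range(1, n_experiments + 1):
        for f in range(1, config.fields_per_experiment + 1):
            spec = synthdata.random_organ_spec(rng, noise_sd=noise_sd)
            spec = dataclasses.replace(spec, um_per_px=config.um_per_px)
            image, gt = synthdata.generate_organ_image(spec)
            p = write_organ_image(images_dir / f"exp{e}_field{f}.tif", image, gt)
            log.output(p, "synthetic organ-culture field")
    log.stage("simulate_images", n_experiments=n_experiments,
              fields_per_experiment=config.fields_per_experiment,
              noise_sd=noise_sd, um_per_px=config.um_per_px)

    levels = PAPER_LIKE_LEVELS
    ct_spec = synthdata.CtGeneratorSpec(
        n_populations=len(levels), pemt_levels=levels,
        noise_sd_cycles=ct_noise_sd_cycles, seed=int(rng.integers(2**31 - 1)),
    )
    ct = synthdata.generate_ct_table(ct_spec)
    ct.to_csv(out / "ct_table.csv", index=False)
    log.output(out / "ct_table.csv", "qPCR Ct table (nine panel genes + GAPDH)")
    pops = ct_spec.population_ids()
    pd.DataFrame({"population_id": pops, "pemt_level": levels}).to_csv(
        out / "populations.csv", index=False
    )

    dens = synthdata.generate_densitometry(
        4, 2, seed=int(rng.integers(2**31 - 1)), noise_sd=0.05
    )
    dens.to_csv(out / "densitometry.csv", index=False)
    log.output(out / "densitometry.csv", "pSMAD3 densitometry (4 responders, 2 non)")

    tf, planted = synthdata.generate_tf_matrix(
        np.asarray(levels), n_tfs=40, planted_r=0.95, seed=int(rng.integers(2**31 - 1))
    )
    tf.index.name = "population_id"
    tf.to_csv(out / "tf_matrix.csv")
    log.output(out / "tf_matrix.csv", f"TF expression matrix (planted: {planted})")

    # LWR fixtures: elongation coupled to the latent p-EMT gradient
    manifest = []
    for pop, level in zip(pops, levels):
        ratios = 1.0 + 2.0 * level + rng.uniform(0.0, 0.3, size=50)
        masks, true_ratios = synthdata.generate_cell_masks(
            50, ratios, seed=int(rng.integers(2**31 - 1))
        )
        stack = np.stack(masks).astype(np.uint8) * 255
        mp = out / f"cellmasks_{pop}.tif"
        tifffile.imwrite(mp, stack, photometric="minisblack")
        for i, tr in enumerate(true_ratios):
            manifest.append((pop, i, float(tr), mp.name, i))
    pd.DataFrame(
        manifest, columns=["population_id", "cell_id", "true_ratio", "file", "page"]
    ).to_csv(out / "cellmask_manifest.csv", index=False)
    log.output(out / "cellmask_manifest.csv", "cell mask manifest (50 cells/population)")

    log.write(out / "provenance_simulate.json")
    return {"output_dir": out, "planted_tf": planted, "populations": pops}


def run_quantify(config: RunConfig) -> dict:
    """Quantify every image field and aggregate per experiment.

    Image stems are grouped into experiments at ``_field``; each experiment's
    fields are averaged into one summary row (warning when != 9 fields).
    """
    out = _outdir(config)
    log = ProvenanceLog(config.asdict())
    images_dir = Path(config.images_dir or out / "images")
    paths = sorted(images_dir.glob("*.tif")) + sorted(images_dir.glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no images found in {images_dir}")

    per_field = []
    results_by_exp: dict[str, list[grading.GradingResult]] = {}
    for p in paths:
        sc = read_sidecar(p)
        um = float(sc["um_per_px"]) if sc and "um_per_px" in sc else config.um_per_px
        image = read_organ_image(p, um_per_px=um)
        q = imagequant.quantify_image(
            image,
            method=config.segmentation_method,
            min_island_area=config.min_island_area,
            min_nucleus_area=config.min_nucleus_area,
            cutoff=config.nuclei_cutoff,
        )
        res = grading.grade_image(
            q["island_table"], q["depth_um"], image_id=p.stem,
            sheet_mask=q["sheet_mask"], sheet_base_row=q["sheet_base_row"],
            cutoff=config.nuclei_cutoff, distance_cutoff_um=config.wpoi_distance_um,
        )
        per_field.append(dataclasses.asdict(res) | {"threshold": q["threshold"], "depth_um": q["depth_um"]})
        exp_id = p.stem.split("_field")[0]
        results_by_exp.setdefault(exp_id, []).append(res)
    log.stage("quantify", n_images=len(paths),
              segmentation_method=config.segmentation_method,
              min_island_area=config.min_island_area,
              min_nucleus_area=config.min_nucleus_area,
              nuclei_cutoff=config.nuclei_cutoff,
              wpoi_distance_um=config.wpoi_distance_um)

    fields_df = pd.DataFrame(per_field)
    fields_df.to_csv(out / "grading_results.csv", index=False)
    log.output(out / "grading_results.csv", "per-field grading")

    summaries = []
    for exp_id, results in sorted(results_by_exp.items()):
        if len(results) != config.fields_per_experiment:
            log.warn(f"experiment {exp_id}: {len(results)} fields, expected "
                     f"{config.fields_per_experiment}")
        summaries.append(dataclasses.asdict(
            grading.aggregate_experiment(results, experiment_id=exp_id)
        ))
    summary_df = pd.DataFrame(summaries)
    summary_df.to_csv(out / "experiment_summaries.csv", index=False)
    log.output(out / "experiment_summaries.csv", "per-experiment means and SEM")
    log.write(out / "provenance_quantify.json")
    return {"fields": fields_df, "summaries": summary_df}


def run_score(config: RunConfig) -> "pd.DataFrame":
    """Score a Ct table; writes per-population scores plus intermediates."""
    from .pemt import pemt_score

    out = _outdir(config)
    log = ProvenanceLog(config.asdict())
    ct_path = Path(config.ct_table or out / "ct_table.csv")
    ct = pd.read_csv(ct_path)
    result = pemt_score(ct)
    result.scores.to_csv(out / "pemt_scores.csv")
    result.per_gene.to_csv(out / "pemt_intermediates.csv")
    log.stage("score", ct_table=str(ct_path))
    log.output(out / "pemt_scores.csv", "per-population p-EMT scores")
    log.output(out / "pemt_intermediates.csv", "per-gene dCT/EXP/N_val/normalized")
    log.write(out / "provenance_score.json")
    return result.scores


def run_associate(
    config: RunConfig,
    metrics: pd.DataFrame,
    pairs: list[tuple[str, str]],
    tf_matrix: pd.DataFrame | None = None,
    phenotype_col: str | None = None,
    plot: bool = False,
) -> pd.DataFrame:
    """Correlate requested metric pairs; optionally run the TF screen.

    ``metrics`` rows must be aligned populations; a constant column yields an
    undefined (NaN) row and the run continues.
    """
    out = _outdir(config)
    log = ProvenanceLog(config.asdict())
    rows = []
    for xc, yc in pairs:
        for c in (xc, yc):
            if c not in metrics.columns:
                raise KeyError(f"metric column {c!r} not in table "
                               f"(have {sorted(metrics.columns)})")
        x, y = metrics[xc].to_numpy(float), metrics[yc].to_numpy(float)
        try:
            res = stats.pearson_with_regression(x, y, xc, yc)
            rows.append({"x": xc, "y": yc, "n": res.n, "r": res.r,
                         "p_value": res.p_value, "slope": res.slope,
                         "intercept": res.intercept})
            if plot:
                _scatter(out / f"assoc_{xc}_vs_{yc}.png", x, y, res)
        except ValueError as err:
            log.warn(f"{xc} vs {yc}: {err}")
            rows.append({"x": xc, "y": yc, "n": len(x), "r": np.nan,
                         "p_value": np.nan, "slope": np.nan, "intercept": np.nan})
    assoc = pd.DataFrame(rows)
    assoc.to_csv(out / "associations.csv", index=False)
    log.output(out / "associations.csv", "pairwise Pearson r/p + OLS lines")

    if tf_matrix is not None and phenotype_col is not None:
        aligned = tf_matrix.reindex(metrics["population_id"]) \
            if "population_id" in metrics.columns and tf_matrix.index.name == "population_id" \
            else tf_matrix
        if aligned.isna().any().any():
            raise ValueError(
                "population labels of the TF matrix do not match the metrics table: "
                f"{sorted(set(metrics['population_id']) ^ set(tf_matrix.index))}"
            )
        screen = stats.tf_screen(aligned, metrics[phenotype_col].to_numpy(float),
                                 phenotype_name=phenotype_col)
        screen.to_csv(out / "tf_screen.csv", index=False)
        log.output(out / "tf_screen.csv", f"TF screen vs {phenotype_col}")
    log.write(out / "provenance_associate.json")
    return assoc


def _scatter(path: Path, x, y, res) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, color="k")
    xs = np.linspace(min(x), max(x), 50)
    ax.plot(xs, res.slope * xs + res.intercept, "r-")
    ax.set_xlabel(res.x_name)
    ax.set_ylabel(res.y_name)
    ax.set_title(f"r={res.r:.3f}, p={res.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_all(config: RunConfig, n_experiments: int = 2, plot: bool = False) -> dict:
    """simulate -> quantify -> score -> LWR -> associate, one output tree."""
    out = _outdir(config)
    sim = run_simulate(config, n_experiments=n_experiments)
    quant = run_quantify(config)
    scores = run_score(config)

    manifest = pd.read_csv(out / "cellmask_manifest.csv")
    lwr_rows = []
    for pop, block in manifest.groupby("population_id"):
        stack = tifffile.imread(out / block["file"].iloc[0]) > 0
        shapes, mean_lwr = imagequant.measure_lwr(list(stack))
        lwr_rows.append((pop, mean_lwr))
    lwr = pd.DataFrame(lwr_rows, columns=["population_id", "mean_lwr"])

    metrics = scores.reset_index().merge(lwr, on="population_id")
    pops = pd.read_csv(out / "populations.csv")
    metrics = metrics.merge(pops, on="population_id")
    metrics.to_csv(out / "metrics.csv", index=False)

    tf = pd.read_csv(out / "tf_matrix.csv", index_col="population_id")
    assoc = run_associate(
        config, metrics, pairs=[("mean_lwr", "score"), ("pemt_level", "score")],
        tf_matrix=tf, phenotype_col="score", plot=plot,
    )
    return {"simulate": sim, "quantify": quant, "scores": scores,
            "metrics": metrics, "associations": assoc}
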