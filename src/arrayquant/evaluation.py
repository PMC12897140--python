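"""Standardized self-evaluation protocols on synthetic ground truth.

These routines measure, from scratch, what the pipeline is supposed to
deliver: geometric recovery (rotation and well localization under known
transforms, warps and noise), end-to-end fold-change recovery through the
full image pipeline, and the small-sample calibration of the Welch test.
They are used by the acceptance checks and are available to users as a
self-test of an installation.

Problem sizes (50 geometric fixtures; an 8-membrane experiment on the
105-analyte layout; 10,000 null analytes) are chosen so the whole battery
runs in a few minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .blob_detection import detect
from .diff_stats import condition_group, differential_table
from .grid_processing import build_grid
from .intensity_measurement import human_xl_map
from .pipeline import locate_wells, run_pipeline
from .synthetic_array import SyntheticArraySpec, render_array, render_experiment


def _order(truth):
    return np.lexsort((truth.cols, truth.rows))


def geometric_recovery(
    seed: int = 0,
    n_clean: int = 20,
    n_warp: int = 15,
    n_noisy: int = 15,
    amplitude: float = 3000.0,
) -> dict:
    """Rotation and well-localization accuracy over seeded random fixtures.

    Three fixture groups, all with rotation in +/-25 degrees, translation
    +/-40 px and scale +/-8%:

    * ``clean``: noiseless, warp-free — isolates the rotation estimator
      (the variance search cannot distinguish a true rotation from the
      tilt a membrane warp induces, so its tolerance is only meaningful
      without warp);
    * ``warp``: noiseless with a 0.5-2 px sinusoidal membrane warp;
    * ``noisy``: warp up to 2 px, 1 px spot placement jitter and pixel
      noise at SNR 10.

    Returns rotation errors (degrees) per group and the fraction of wells
    localized within 1 px (clean + warp pooled) and 2 px (noisy).
    """
    rng = np.random.default_rng(seed)
    base = SyntheticArraySpec(
        n_rows=8, n_cols=10, pitch=30.0, margin=140,
        amplitudes=np.full((8, 10), amplitude), seed=int(rng.integers(2**31)),
    )
    template, _ = build_grid(detect(render_array(base)[0]))

    rot_err = {"clean": [], "warp": [], "noisy": []}
    loc_err = {"clean": [], "warp": [], "noisy": []}
    groups = ["clean"] * n_clean + ["warp"] * n_warp + ["noisy"] * n_noisy
    for i, group in enumerate(groups):
        theta = float(rng.uniform(-25, 25))
        spec = replace(
            base,
            theta=theta,
            tx=float(rng.uniform(-40, 40)),
            ty=float(rng.uniform(-40, 40)),
            scale=float(rng.uniform(0.92, 1.08)),
            warp_amplitude=(
                0.0 if group == "clean" else float(rng.uniform(0.5, 2.0))
                if group == "warp" else float(rng.uniform(0.0, 2.0))
            ),
            jitter_sd=1.0 if group == "noisy" else 0.0,
            noise_sd=amplitude / 10.0 if group == "noisy" else 0.0,
            seed=int(rng.integers(2**31)),
        )
        image, truth = render_array(spec)
        positions, rot, _ = locate_wells(image, template, seed=int(rng.integers(2**31)))
        rot_err[group].append(abs(rot.angle + theta))
        err = np.linalg.norm(positions - truth.positions[_order(truth)], axis=1)
        loc_err[group].append(err)

    pooled_1px = np.concatenate(loc_err["clean"] + loc_err["warp"])
    noisy = (
        np.concatenate(loc_err["noisy"]) if loc_err["noisy"] else np.array([np.nan])
    )
    return {
        "n_fixtures": len(groups),
        "rotation_max_error_clean_deg": float(np.max(rot_err["clean"])),
        "rotation_max_error_noisy_deg": float(np.max(rot_err["noisy"])),
        "wells_within_1px_frac": float((pooled_1px < 1.0).mean()),
        "wells_within_2px_noisy_frac": float((noisy < 2.0).mean()),
        "n_wells_clean": int(pooled_1px.size),
        "n_wells_noisy": int(noisy.size),
    }


#: injected log2 fold-change design of the standard recovery experiment:
#: (log2FC level, number of analytes), assigned to the panel in sorted order
EFFECT_DESIGN = ((2.0, 20), (-2.0, 20), (1.0, 5), (-1.0, 5), (0.0, 55))


def effect_recovery(seed: int = 0, cv: float = 0.10, n_replicates: int = 4) -> dict:
    """Full-pipeline fold-change recovery on a 2-condition experiment.

    Renders ``n_replicates`` membranes per condition of the packaged
    105-analyte layout with the :data:`EFFECT_DESIGN` injected effects and
    per-spot lognormal intensity noise of coefficient of variation ``cv``,
    runs the complete image pipeline (template from the first membrane),
    and compares the estimated per-analyte log2 fold-changes and the joint
    significance gate (|log2FC| > 1 and Z > 0.5) against the truth.

    Effect levels are assigned to a seeded random permutation of the
    panel, scattering regulated analytes across the membrane as in a real
    experiment (adjacent map positions hold alphabetically close analytes,
    so an in-order assignment would concentrate down-regulated — hence
    faint — spots in one grid region).
    """
    amap = human_xl_map()
    rng = np.random.default_rng(seed)
    analytes = [str(a) for a in rng.permutation(amap.analytes)]
    effects: dict[str, float] = {}
    k = 0
    for level, count in EFFECT_DESIGN:
        for a in analytes[k : k + count]:
            effects[a] = level
        k += count
    base = SyntheticArraySpec(
        n_rows=10, n_cols=24, pitch=24.0, margin=45, noise_sd=60.0,
    )
    conds, truth = render_experiment(
        base, amap, effects, n_replicates=n_replicates, cv=cv, seed=seed
    )
    images = [im for im, _ in conds["treated"]] + [im for im, _ in conds["reference"]]
    results, _ = run_pipeline(images, amap, seed=seed)
    treated = condition_group([r.analytes for r in results[:n_replicates]])
    reference = condition_group([r.analytes for r in results[n_replicates:]])
    table = differential_table(treated, reference).merge(
        truth, on="analyte", suffixes=("", "_true")
    )
    err = (table["log2FC"] - table["log2FC_true"]).abs()
    strong = table[table["log2FC_true"].abs() == 2.0]
    null = table[table["log2FC_true"] == 0.0]
    return {
        "table": table,
        "n_analytes": len(table),
        "log2fc_max_abs_error": float(err.max()),
        "log2fc_mean_abs_error": float(err.mean()),
        "power_at_twofold": float(strong["significant"].mean()),
        "n_twofold": int(len(strong)),
        "false_flag_rate": float(null["significant"].mean()),
        "n_null": int(len(null)),
    }


def welch_null_calibration(
    seed: int = 0, n_analytes: int = 10000, n_per_group: int = 4, alpha: float = 0.01
) -> dict:
    """Fraction of null analytes with Welch p below ``alpha``.

    Small-sample t calibration check: equal-mean lognormal groups of size
    ``n_per_group``; a calibrated test rejects at close to ``alpha``.
    """
    rng = np.random.default_rng(seed)
    a = rng.lognormal(0.0, 0.1, (n_analytes, n_per_group))
    b = rng.lognormal(0.0, 0.1, (n_analytes, n_per_group))
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return {
        "fraction_below_alpha": float((res.pvalue < alpha).mean()),
        "n_analytes": n_analytes,
    }
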