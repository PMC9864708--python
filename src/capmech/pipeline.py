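"""End-to-end orchestration: cohort -> morphology -> mechanics -> PVI -> RF.

Each stage is a plain function over the library types so tests, the CLI and
the analysis scripts share one code path.  ``run_pipeline`` chains them with
per-stage CSV caching inside a run directory and a manifest recording the
configuration, seed and timings.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fem, predict, pvi, zero_load
from .contours import (
    SliceContours,
    cap_thickness_profile,
    make_cap_samples,
    morphology,
    read_slice,
    write_slice,
)
from .materials import DEFAULT_MATERIALS, MaterialParams
from .mesh import build_mesh
from .synthetic import CohortSpec, SlicePair, generate_cohort

__all__ = [
    "MMHG_TO_KPA",
    "MechanicsSettings",
    "RunConfig",
    "slice_mechanics",
    "cohort_tables",
    "pvi_records",
    "feature_table",
    "run_pipeline",
]

MMHG_TO_KPA = 0.1333224

# which measurement feeds each vulnerability index
INDEX_MEASUREMENTS = {
    "C": "MinCapT",
    "MaxS": "MaxCapS",
    "MeanS": "MeanCapS",
    "MaxSn": "MaxCapSn",
    "MeanSn": "MeanCapSn",
}


@dataclass(frozen=True)
class MechanicsSettings:
    """Numerical settings of the per-slice mechanics stage.

    The defaults favour throughput for cohort work: a coarse mesh drives
    the zero-load search and a boundary-layer-graded mesh the final solve.
    Validation work against the tube oracle uses finer sizes explicitly.
    """

    element_size: float = 0.3  # mm, final solve (graded at the lumen)
    coarse_mesh_size: float = 0.45  # mm, shrink bisection
    shrink_tol: float = 0.02  # relative lumen-area mismatch
    n_increments: int = 4
    axial_shrink: float = 0.05
    pressure_choice: str = "sys"  # stress/strain under maximum pressure

    @property
    def axial_stretch(self) -> float:
        return 1.0 / (1.0 - self.axial_shrink)


def slice_pressure_kpa(slc: SliceContours, choice: str = "sys") -> float:
    if not slc.pressure_mmHg or choice not in slc.pressure_mmHg:
        raise ValueError(f"slice {slc.slice_id}: no {choice!r} pressure")
    return float(slc.pressure_mmHg[choice]) * MMHG_TO_KPA


def slice_mechanics(
    slc: SliceContours,
    materials: dict[str, MaterialParams] | None = None,
    settings: MechanicsSettings = MechanicsSettings(),
) -> dict:
    """Zero-load recovery, FE solve and cap stress/strain for one slice.

    Returns a record with the four mechanical predictors (None when the
    slice has no fibrous cap), the fitted circumferential shrink and the
    achieved lumen-area round-trip error.
    """
    materials = materials or DEFAULT_MATERIALS
    pressure = slice_pressure_kpa(slc, settings.pressure_choice)
    guess = zero_load.estimate_circ_shrink_annulus(
        slc, pressure, settings.axial_shrink
    )
    try:
        shrink = zero_load.find_circ_shrink(
            slc,
            materials,
            pressure,
            tol=settings.shrink_tol,
            coarse_mesh_size=settings.coarse_mesh_size,
            axial_shrink=settings.axial_shrink,
            n_increments=settings.n_increments,
            initial_guess=guess,
        )
    except RuntimeError:
        # warm-started bracket failed (e.g. FE non-convergence near the
        # guess): retry over the full bracket with gentler load stepping
        shrink = zero_load.find_circ_shrink(
            slc,
            materials,
            pressure,
            tol=settings.shrink_tol,
            coarse_mesh_size=settings.coarse_mesh_size,
            axial_shrink=settings.axial_shrink,
            n_increments=max(8, settings.n_increments),
        )
    mesh = build_mesh(shrink.shrunk, settings.element_size, boundary_layer=True)
    solution = fem.solve(
        mesh, materials, pressure, settings.axial_stretch,
        n_increments=settings.n_increments,
    )
    samples = make_cap_samples(slc)
    if slc.has_lipid:
        samples = cap_thickness_profile(slc, samples)
    filled = fem.extract_cap_mechanics(solution, samples)
    rec = fem.cap_mechanics_record(filled)
    rec.update(
        slice_id=slc.slice_id,
        timepoint=slc.timepoint,
        circ_shrink=shrink.circ_shrink,
        lumen_area_error=shrink.achieved_lumen_area_error,
        pressure_kPa=pressure,
    )
    return rec


def cohort_tables(
    pairs: list[SlicePair],
    materials: dict[str, MaterialParams] | None = None,
    settings: MechanicsSettings = MechanicsSettings(),
    verbose: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Morphology and mechanics tables for all slices of a cohort.

    Rows are indexed by (slice_id, timepoint); mechanics involves two FE
    model solves per matched pair.
    """
    morph_rows, mech_rows = [], []
    for i, pair in enumerate(pairs):
        for slc in (pair.baseline, pair.followup):
            m = morphology(slc)
            morph_rows.append(
                {
                    "slice_id": slc.slice_id,
                    "timepoint": slc.timepoint,
                    "LA": m.LA,
                    "PA": m.PA,
                    "PB": m.PB,
                    "MinCapT": m.MinCapT,
                    "MeanCapT": m.MeanCapT,
                }
            )
            mech_rows.append(slice_mechanics(slc, materials, settings))
        if verbose and (i + 1) % 10 == 0:
            print(f"  mechanics: {i + 1}/{len(pairs)} pairs")
    morph = pd.DataFrame(morph_rows).set_index(["slice_id", "timepoint"])
    mech = pd.DataFrame(mech_rows).set_index(["slice_id", "timepoint"])
    return morph, mech


def pvi_records(
    morph: pd.DataFrame,
    mech: pd.DataFrame,
    thresholds: dict[str, pvi.PviThresholds] | None = None,
    calibrate: bool = False,
) -> pd.DataFrame:
    """Score the five indices per matched pair and derive delta/binary.

    With ``calibrate=True`` the stress/strain cuts are re-derived from the
    pooled baseline+follow-up measurements against the cap-based
    categories; the cap index always uses its fixed cuts.
    """
    table = morph.join(mech.drop(columns=[c for c in mech.columns
                                          if c in morph.columns]),
                       how="inner")
    values = {
        name: table[INDEX_MEASUREMENTS[name]] for name in pvi.INDEX_NAMES
    }
    thresholds = dict(thresholds or pvi.DEFAULT_THRESHOLDS)
    valid = ~values["C"].isna()
    if calibrate:
        c_labels = [
            pvi.score_pvi(v, thresholds["C"]) for v in values["C"][valid]
        ]
        for name in ("MaxS", "MeanS", "MaxSn", "MeanSn"):
            thresholds[name] = pvi.calibrate_thresholds(
                values[name][valid].to_numpy(), c_labels, name
            )
    rows = []
    slice_ids = table.index.get_level_values("slice_id").unique()
    for sid in slice_ids:
        try:
            base = table.loc[(sid, "baseline")]
            fu = table.loc[(sid, "followup")]
        except KeyError:
            warnings.warn(f"{sid}: unmatched pair; skipped", stacklevel=2)
            continue
        if any(pd.isna(base[m]) or pd.isna(fu[m])
               for m in INDEX_MEASUREMENTS.values()):
            continue  # no lipid core at one timepoint: no cap, excluded
        row: dict = {"slice_id": sid}
        for name, meas in INDEX_MEASUREMENTS.items():
            b = pvi.score_pvi(float(base[meas]), thresholds[name])
            f = pvi.score_pvi(float(fu[meas]), thresholds[name])
            delta, binary = pvi.delta_binary(b, f)
            row[f"{name}_baseline"] = b
            row[f"{name}_followup"] = f
            row[f"{name}_delta"] = delta
            row[f"{name}_binary"] = binary
        rows.append(row)
    return pd.DataFrame(rows).set_index("slice_id")


def feature_table(
    morph: pd.DataFrame,
    mech: pd.DataFrame,
    records: pd.DataFrame,
    index_name: str = "C",
) -> predict.FeatureTable:
    """Baseline 9-predictor table with the chosen index's binary outcome."""
    base_m = morph.xs("baseline", level="timepoint")
    base_k = mech.xs("baseline", level="timepoint")[
        ["MaxCapS", "MeanCapS", "MaxCapSn", "MeanCapSn"]
    ]
    outcomes = records[f"{index_name}_binary"]
    common = base_m.join(base_k).reindex(records.index)
    return predict.assemble_features(
        common[["LA", "PA", "PB", "MinCapT", "MeanCapT"]],
        common[["MaxCapS", "MeanCapS", "MaxCapSn", "MeanCapSn"]],
        outcomes,
        index_name,
    )


# ---------------------------------------------------------------------------
# full pipeline with caching
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One pipeline run: cohort source, mechanics, thresholds, RF settings."""

    out_dir: str
    input_dir: str | None = None  # read contour JSONs instead of generating
    cohort: CohortSpec = field(default_factory=CohortSpec)
    mechanics: MechanicsSettings = field(default_factory=MechanicsSettings)
    thresholds_mode: str = "table"  # "table" | "calibrate"
    indices: tuple[str, ...] = ("C",)
    n_trees: int = 50
    n_repeats: int = 100
    sweep: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_pairs(config: RunConfig) -> list[SlicePair]:
    if config.input_dir is not None:
        indir = Path(config.input_dir)
        if not indir.is_dir():
            raise FileNotFoundError(f"input dir {indir} does not exist")
        slices = [read_slice(p) for p in sorted(indir.glob("*.json"))]
        by_id: dict[str, dict] = {}
        for s in slices:
            by_id.setdefault(s.slice_id, {})[s.timepoint] = s
        pairs = []
        for sid, tps in sorted(by_id.items()):
            if set(tps) != {"baseline", "followup"}:
                warnings.warn(f"{sid}: missing timepoint; skipped", stacklevel=2)
                continue
            pairs.append(SlicePair(tps["baseline"], tps["followup"],
                                   (np.nan, np.nan)))
        return pairs
    spec = config.cohort
    if spec.seed != config.seed:
        spec = CohortSpec(**{**asdict(spec), "seed": config.seed,
                             "progression": spec.progression})
    return generate_cohort(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, caching per-stage CSVs under the run directory.

    Returns a results bundle: stage tables plus per-index prediction
    results; a manifest JSON records the config hash, seed and timings.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    timings: dict[str, float] = {}

    def cached(name: str) -> Path:
        return out / f"{name}.{chash}.csv"

    t0 = time.time()
    pairs = _load_pairs(config)
    timings["cohort"] = time.time() - t0

    contour_dir = out / "contours"
    contour_dir.mkdir(exist_ok=True)
    for pair in pairs:
        for slc in (pair.baseline, pair.followup):
            write_slice(slc, contour_dir / f"{slc.slice_id}_{slc.timepoint}.json")

    t0 = time.time()
    if cached("morph").exists() and cached("mech").exists():
        morph = pd.read_csv(cached("morph"), index_col=[0, 1])
        mech = pd.read_csv(cached("mech"), index_col=[0, 1])
    else:
        morph, mech = cohort_tables(pairs, None, config.mechanics)
        morph.to_csv(cached("morph"))
        mech.to_csv(cached("mech"))
    timings["mechanics"] = time.time() - t0

    t0 = time.time()
    records = pvi_records(
        morph, mech, calibrate=(config.thresholds_mode == "calibrate")
    )
    records.to_csv(out / "pvi.csv")
    timings["pvi"] = time.time() - t0

    t0 = time.time()
    predictions: dict[str, dict] = {}
    for index_name in config.indices:
        try:
            table = feature_table(morph, mech, records, index_name)
        except ValueError as e:
            warnings.warn(f"{index_name}: prediction skipped ({e})", stacklevel=2)
            continue
        if config.sweep:
            results = predict.sweep_combinations(
                table, config.n_trees, config.n_repeats, config.seed
            )
            single, combo = predict.best_single_and_combination(results)
            predictions[index_name] = {
                "results": results,
                "best_single": single,
                "best_combination": combo,
            }
        else:
            res = predict.evaluate_subset(
                table, predict.FEATURE_NAMES, config.n_trees,
                config.n_repeats, config.seed,
            )
            predictions[index_name] = {"results": [res],
                                       "best_combination": res}
        rows = [
            {
                "predictors": "+".join(r.predictor_subset),
                "acc": r.acc, "sen": r.sen, "spe": r.spe,
                "sen_plus_spe": r.sen_plus_spe, "auc": r.auc,
            }
            for r in predictions[index_name]["results"]
        ]
        pd.DataFrame(rows).to_csv(out / f"predictions_{index_name}.csv",
                                  index=False)
    timings["prediction"] = time.time() - t0

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "n_pairs": len(pairs),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "config": json.loads(json.dumps(asdict(config), default=str)),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {
        "pairs": pairs,
        "morph": morph,
        "mech": mech,
        "pvi": records,
        "predictions": predictions,
        "manifest": manifest,
    }
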