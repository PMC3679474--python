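"""Study orchestration: configuration, validation, and the full pipeline.

``run_all`` drives generate (optional) -> morphometry -> mechanics ->
expression -> stats over an on-disk study bundle (the layout written by
:func:`lungquant.synthetic_data.generate_cohort`) and writes tidy CSV
outputs, each stamped with the configuration hash and seed.  Stages are
individually callable and idempotent, so a bundle can be re-analysed
from persisted intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import expression as expr
from . import mechanics as mech
from . import morphometry as morph
from . import stats as st
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A stage failed; the message names the stage and offending record."""


@dataclass(frozen=True)
class PipelineConfig:
    input_dir: str = "cohort"
    output_dir: str = "results"
    # morphometry
    spacing_px: int = morph.DEFAULT_SPACING_PX
    min_area_px: int = morph.DEFAULT_MIN_AREA_PX
    px_per_micron: float = morph.DEFAULT_PX_PER_MICRON
    count_direction: str = "air_to_tissue"
    # mechanics
    cst_pressure: float = 5.0
    tlc_pressure: float = 30.0
    # stats
    alpha: float = 0.05
    comparisons: tuple[tuple[str, str], ...] = st.DEFAULT_COMPARISONS
    family_size: int | None = None
    # generation
    seed: int = 0
    generate: bool = False
    mice_per_group: int = 11
    images_per_mouse: int = 10
    image_width: int = 1600
    image_height: int = 1200

    def __post_init__(self) -> None:
        for name in ("spacing_px", "min_area_px", "px_per_micron", "cst_pressure",
                     "tlc_pressure", "alpha", "mice_per_group", "images_per_mouse",
                     "image_width", "image_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"config key {name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(p) for p in raw["comparisons"])
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        configuration hashes identically wherever it reads or writes)."""
        payload = dataclasses.asdict(self)
        payload.pop("input_dir")
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stamp_and_write(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.content_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(bundle_dir: str | Path) -> list[dict]:
    """Check a study bundle; returns a machine-readable list of findings.

    Checks: design.csv presence/schema, every animal in exactly one group,
    image readability (a truncated PNG is named in a finding), images
    belonging to animals present in the design, and the schemas of the
    expression/pathology/mechanics CSVs.  An empty list means the bundle
    is well formed.
    """
    bundle = Path(bundle_dir)
    findings: list[dict] = []

    def finding(kind: str, message: str, path: str | None = None) -> None:
        findings.append({"kind": kind, "message": message, "path": path})

    design_path = bundle / "design.csv"
    animals: set[str] = set()
    if not design_path.exists():
        finding("missing_file", "design.csv not found", str(design_path))
    else:
        design = pd.read_csv(design_path)
        required = {"animal_id", "group", "diet", "smoke"}
        missing = required - set(design.columns)
        if missing:
            finding("schema", f"design.csv missing columns {sorted(missing)}",
                    str(design_path))
        else:
            dup = design["animal_id"][design["animal_id"].duplicated()]
            for a in dup:
                finding("design", f"animal {a!r} appears more than once",
                        str(design_path))
            animals = set(design["animal_id"])

    image_dir = bundle / "images"
    if image_dir.exists():
        for img_path in sorted(image_dir.glob("*.png")):
            try:
                with Image.open(img_path) as im:
                    im.verify()
            except Exception as exc:
                finding("unreadable_image", f"cannot read {img_path.name}: {exc}",
                        str(img_path))
                continue
            animal = img_path.stem.rsplit("_img", 1)[0]
            if animals and animal not in animals:
                finding("orphan_image",
                        f"image {img_path.name} has no animal {animal!r} in design.csv",
                        str(img_path))

    for name, required in (
        ("expression.csv", {"animal_id", "gene", "ct"}),
        ("pathology.csv", {"animal_id", "feature", "score"}),
    ):
        path = bundle / name
        if path.exists():
            df = pd.read_csv(path)
            missing = required - set(df.columns)
            if missing:
                finding("schema", f"{name} missing columns {sorted(missing)}", str(path))
    return findings


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_morphometry(config: PipelineConfig, bundle: Path, out: Path) -> pd.DataFrame:
    cfg = morph.MorphometryConfig(
        spacing_px=config.spacing_px, min_area_px=config.min_area_px,
        px_per_micron=config.px_per_micron,
        count_direction=config.count_direction,  # type: ignore[arg-type]
    )
    design = pd.read_csv(bundle / "design.csv").set_index("animal_id")
    rows = []
    skipped = 0
    for img_path in sorted((bundle / "images").glob("*.png")):
        animal = img_path.stem.rsplit("_img", 1)[0]
        if animal not in design.index:
            raise PipelineError(f"morphometry: image {img_path.name} maps to no animal")
        arr = np.asarray(Image.open(img_path).convert("RGB"))
        image = morph.CalibratedImage(pixels=arr, px_per_micron=config.px_per_micron)
        try:
            res = morph.mli_for_image(image, cfg)
        except morph.MorphometryError as exc:
            logger.warning("morphometry: skipping %s (%s)", img_path.name, exc)
            skipped += 1
            continue
        rows.append({
            "image": img_path.name, "animal_id": animal,
            "group": design.loc[animal, "group"],
            "diet": design.loc[animal, "diet"], "smoke": design.loc[animal, "smoke"],
            "n_lines": res.counts.n_lines, "line_length_px": res.counts.line_length_px,
            "sum_I": res.counts.transitions, "lm_um": res.lm_um,
        })
    per_image = pd.DataFrame(rows)
    if per_image.empty:
        raise PipelineError("morphometry: no images produced a valid L_M")
    per_mouse, per_group = morph.aggregate(per_image)
    per_group_images = morph.aggregate_image_level(per_image)
    _stamp_and_write(per_image, out / "mli_per_image.csv", config)
    _stamp_and_write(per_mouse, out / "mli_per_mouse.csv", config)
    _stamp_and_write(per_group, out / "mli_per_group.csv", config)
    _stamp_and_write(per_group_images, out / "mli_per_group_imagelevel.csv", config)
    logger.info("morphometry: %d images processed, %d skipped", len(per_image), skipped)
    return per_image


def run_mechanics(config: PipelineConfig, bundle: Path, out: Path) -> pd.DataFrame:
    design = pd.read_csv(bundle / "design.csv")
    rows = []
    for _, animal in design.iterrows():
        aid = animal["animal_id"]
        row = {"animal_id": aid, "group": animal["group"],
               "diet": animal["diet"], "smoke": animal["smoke"]}
        try:
            pv = pd.read_csv(bundle / "mechanics" / f"{aid}_pv.csv")
            inf = pv[pv["limb"] == "inflation"].sort_values("pressure")
            dfl = pv[pv["limb"] == "deflation"].sort_values("pressure")
            loop = mech.PVLoop(
                pressure=inf["pressure"].to_numpy(),
                volume_inflation=inf["volume"].to_numpy(),
                volume_deflation=dfl["volume"].to_numpy(),
            )
            met = mech.pv_metrics(loop, cst_pressure=config.cst_pressure,
                                  tlc_pressure=config.tlc_pressure)
            row.update({"Cst": met.Cst, "TLC": met.TLC, "Area": met.area,
                        "pv_A": met.A, "pv_B": met.B, "pv_K": met.K})

            imp = pd.read_csv(bundle / "mechanics" / f"{aid}_impedance.csv")
            spec = mech.ImpedanceSpectrum(
                freqs=imp["freq"].to_numpy(),
                Z=imp["z_real"].to_numpy() + 1j * imp["z_imag"].to_numpy(),
            )
            cp = mech.fit_constant_phase(spec)
            row.update({"Rn": cp.Rn, "Iaw": cp.Iaw, "G": cp.G, "H": cp.H,
                        "alpha": cp.alpha})

            ts = pd.read_csv(bundle / "mechanics" / f"{aid}_timeseries.csv")
            rec = mech.PerturbationRecord(
                time=ts["time"].to_numpy(), pressure=ts["pressure"].to_numpy(),
                flow=ts["flow"].to_numpy(), volume=ts["volume"].to_numpy(),
            )
            sc = mech.fit_single_compartment(rec)
            row.update({"R": sc.R, "C": sc.C, "P0": sc.P0})
        except (OSError, mech.MechanicsError, KeyError) as exc:
            raise PipelineError(f"mechanics: animal {aid}: {exc}") from exc
        rows.append(row)
    fits = pd.DataFrame(rows)
    _stamp_and_write(fits, out / "mechanics_fits.csv", config)
    return fits


def run_expression(config: PipelineConfig, bundle: Path, out: Path) -> pd.DataFrame:
    table = pd.read_csv(bundle / "expression.csv")
    rel = expr.relative_expression(table)
    per_animal, per_group = expr.mmp9_timp1_ratio(rel)
    _stamp_and_write(rel, out / "relative_expression.csv", config)
    _stamp_and_write(per_animal, out / "mmp9_timp1_ratio.csv", config)
    _stamp_and_write(per_group, out / "mmp9_timp1_ratio_groups.csv", config)
    return per_animal


def run_stats(
    config: PipelineConfig,
    out: Path,
    per_image_mli: pd.DataFrame,
    mechanics_fits: pd.DataFrame,
    ratios: pd.DataFrame,
    pathology: pd.DataFrame,
) -> dict:
    """ANOVA + planned comparisons on every continuous endpoint, and
    Kruskal-Wallis on the binarised pathology features."""
    anova_rows, comp_frames, summary_frames = [], [], []

    per_mouse, _ = morph.aggregate(per_image_mli)
    endpoints: list[tuple[str, pd.DataFrame]] = [("lm_um", _with_factors(per_mouse))]
    for var in ("Cst", "TLC", "Area", "Rn", "G", "H", "R", "C"):
        if var in mechanics_fits.columns:
            df = mechanics_fits.rename(columns={var: "value"})[
                ["animal_id", "group", "diet", "smoke", "value"]].copy()
            endpoints.append((var, df))
    if not ratios.empty:
        endpoints.append(("mmp9_timp1", _with_factors(
            ratios.rename(columns={"ratio": "lm_um"}))))

    for name, df in endpoints:
        df = df.rename(columns={"lm_um": "value"}) if "lm_um" in df.columns else df
        res = st.two_way_anova(df)
        for effect in ("diet", "smoke", "interaction"):
            e = getattr(res, effect)
            anova_rows.append({"variable": name, "effect": effect, "ss": e.ss,
                               "df": e.df, "F": e.F, "p": e.p})
        comps = st.planned_comparisons(df, pairs=config.comparisons,
                                       family_size=config.family_size)
        comps.insert(0, "variable", name)
        comp_frames.append(comps)
        summ = st.group_summary(df)
        summ.insert(0, "variable", name)
        summary_frames.append(summ)

    kw_rows = []
    scores = st.binarize_scores(pathology)
    for feature in sorted(scores["feature"].unique()):
        H, p = st.kruskal_wallis(scores, feature=feature)
        kw_rows.append({"feature": feature, "H": H, "p": p})

    anova_df = pd.DataFrame(anova_rows)
    comps_df = pd.concat(comp_frames, ignore_index=True)
    summary_df = pd.concat(summary_frames, ignore_index=True)
    kw_df = pd.DataFrame(kw_rows)
    _stamp_and_write(anova_df, out / "anova.csv", config)
    _stamp_and_write(comps_df, out / "planned_comparisons.csv", config)
    _stamp_and_write(summary_df, out / "group_summaries.csv", config)
    _stamp_and_write(kw_df, out / "kruskal_wallis.csv", config)
    return {"anova": anova_df, "comparisons": comps_df,
            "summaries": summary_df, "kruskal_wallis": kw_df}


def _with_factors(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if "diet" not in out.columns or "smoke" not in out.columns:
        parts = out["group"].map(synth.split_group_label)
        out["diet"] = parts.map(lambda t: t[0])
        out["smoke"] = parts.map(lambda t: t[1])
    return out


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> dict:
    """Execute the whole study pipeline; returns the in-memory results.

    Stages: (optional) synthetic-cohort generation, morphometry over all
    images, per-animal mechanics fits, expression normalisation and
    ratios, then the factorial statistics.  A plain-text ``run.log`` with
    ISO timestamps and per-stage counts is written next to the CSVs.
    """
    bundle = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        line = f"{datetime.now(timezone.utc).isoformat()} {msg}"
        log_lines.append(line)
        logger.info(msg)

    log(f"run_all start config_hash={config.content_hash()} seed={config.seed}")

    if config.generate:
        design = synth.CohortDesign(
            mice_per_group=config.mice_per_group,
            images_per_mouse=config.images_per_mouse,
            parenchyma=synth.ParenchymaParams(
                image_width=config.image_width, image_height=config.image_height,
                px_per_micron=config.px_per_micron,
            ),
            master_seed=config.seed,
        )
        synth.generate_cohort(design, bundle)
        log(f"generate: wrote cohort to {bundle}")

    findings = validate_inputs(bundle)
    errors = [f for f in findings if f["kind"] != "orphan_image"]
    if errors:
        raise PipelineError(f"validation failed: {errors[0]['message']}")

    per_image = run_morphometry(config, bundle, out)
    log(f"morphometry: {len(per_image)} images processed")

    fits = run_mechanics(config, bundle, out)
    log(f"mechanics: {len(fits)} animals fitted")

    ratios = run_expression(config, bundle, out)
    log(f"expression: {len(ratios)} animals with MMP9:TIMP1 ratio")

    pathology = pd.read_csv(bundle / "pathology.csv")
    results = run_stats(config, out, per_image, fits, ratios, pathology)
    log("stats: ANOVA, planned comparisons, Kruskal-Wallis written")

    log("run_all done")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results.update({"per_image_mli": per_image, "mechanics_fits": fits,
                    "ratios": ratios, "n_images": len(per_image)})
    return results
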