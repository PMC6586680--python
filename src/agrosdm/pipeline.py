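"""Reproducible end-to-end pipeline.

Stages run in order — simulate, clean, thin, pseudoabs, vif, fit, project,
integrate, analyze — against a run directory of plain-text artifacts
(ASCII rasters, CSV tables, JSON manifests). A single mandatory global
seed is fanned out to per-stage child seeds by stable hashing, so a rerun
with the same config and seed is bit-reproducible; each stage can also be
re-run individually, rebuilding any in-memory state it needs
deterministically from the run directory.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import change as ch
from . import io as aio
from .ensemble import binarize, fit_ensemble, predict_consensus
from .grid import GridSpec, PredictorStack, is_temperature_like
from .learners import default_learners
from .occurrences import (OccurrenceSet, clean_occurrences, sample_pseudo_absences,
                          thin_systematic)
from .projection import project_and_integrate
from .synthetic import (ScenarioSpec, VirtualSpecies, generate_future_stacks,
                        generate_predictor_stack, make_virtual_species,
                        sample_occurrences, true_suitability)
from .vif import select_predictors_vif

STAGES = ["simulate", "clean", "thin", "pseudoabs", "vif", "fit",
          "project", "integrate", "analyze"]

_DEFAULTS = {
    "layers": ["bio02", "bio03", "bio08", "bio09", "bio13", "bio14", "bio15",
               "bio18", "bio19"],
    "add_collinear": [],
    "min_year": 1960,
    "thin_cell": None,            # default: grid resolution
    "n_pseudo_absences": 1000,
    "k_folds": 4,
    "weight_cutoff": 0.05,
    "vif_threshold": 10.0,
    "vif_sample": 10000,
    "agreement": 0.66,
    "elevation_bin_width": 100.0,
    "portfolio": {"rich_total": 30, "rich_per_group": 10, "low_cutoff": 3},
    "crops": [],
    "learners": None,             # default: full registry
    "contaminate": True,
    "write_gcm_maps": False,
}


def child_seed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{label}|{seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    """Fill defaults and reject out-of-range parameters."""
    cfg = dict(_DEFAULTS)
    cfg.update(config)
    if "seed" not in cfg:
        raise ValueError("config must set a seed")
    if "grid" not in cfg or "species" not in cfg or "scenarios" not in cfg:
        raise ValueError("config must define grid, species and scenarios")
    if not (0.5 < cfg["agreement"] <= 1.0):
        raise ValueError("agreement must be in (0.5, 1]")
    if cfg["k_folds"] < 2:
        raise ValueError("k_folds must be >= 2")
    if not (0 <= cfg["weight_cutoff"] < 1):
        raise ValueError("weight_cutoff must be in [0, 1)")
    if cfg["vif_threshold"] <= 1:
        raise ValueError("vif_threshold must be > 1")
    if cfg["n_pseudo_absences"] < 1:
        raise ValueError("n_pseudo_absences must be >= 1")
    names = [s["name"] for s in cfg["species"]]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names")
    for crop in cfg["crops"]:
        if crop not in names:
            raise ValueError(f"crop {crop!r} is not a configured species")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


class PipelineRun:
    """One pipeline execution rooted at a run directory."""

    def __init__(self, config: dict, run_dir):
        self.cfg = validate_config(config)
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.cfg["seed"])
        self.hash = config_hash(self.cfg)
        self._stack: PredictorStack | None = None
        self._species: dict[str, VirtualSpecies] = {}
        self._calibrations: dict = {}
        self._baseline_binary: dict[str, np.ndarray] = {}
        self._integrated: dict[tuple[str, str], np.ndarray] = {}

    # ---------- bookkeeping ----------

    def _log(self, stage: str, **info) -> None:
        rec = {"stage": stage, "config_hash": self.hash, **info}
        with open(self.run_dir / "log.jsonl", "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")

    def _grid(self) -> GridSpec:
        g = self.cfg["grid"]
        return GridSpec.from_origin(g["n_rows"], g["n_cols"], g["x_min"],
                                    g["y_max"], g["resolution"])

    def stack(self) -> PredictorStack:
        if self._stack is None:
            land = self.run_dir / "landscape"
            if not (land / "layers.json").exists():
                self.stage_simulate()
            else:
                self._stack = aio.read_stack(land)
        return self._stack

    def _species_cfgs(self) -> list[dict]:
        return self.cfg["species"]

    def _scenario_specs(self) -> list[ScenarioSpec]:
        out = []
        for sc in self.cfg["scenarios"]:
            out.append(ScenarioSpec(
                name=sc["name"], mean_shift=dict(sc.get("mean_shift", {})),
                gcm_count=int(sc.get("gcm_count", 17)),
                gcm_spread=dict(sc.get("gcm_spread", {})),
                seed=child_seed(self.seed, f"scenario:{sc['name']}")))
        return out

    def _occ_csv(self, name: str, stage: str) -> Path:
        return self.run_dir / "occurrences" / f"{name}_{stage}.csv"

    def _read_occ(self, name: str, stage: str) -> OccurrenceSet:
        df = aio.read_occurrences(self._occ_csv(name, stage))
        return OccurrenceSet(species=name, presences=df)

    # ---------- stages ----------

    def stage_simulate(self) -> None:
        """Generate landscape, virtual species, raw occurrences, futures."""
        grid = self._grid()
        stack = generate_predictor_stack(
            grid, self.cfg["layers"], seed=child_seed(self.seed, "landscape"))
        # derived collinear layers give the VIF screen something to remove
        rng = np.random.default_rng(child_seed(self.seed, "collinear"))
        for spec in self.cfg["add_collinear"]:
            arr = np.zeros(grid.shape)
            for parent, w in zip(spec["parents"], spec["weights"]):
                arr = arr + w * np.nan_to_num(stack.layers[parent])
            arr = arr + spec.get("noise", 0.05) * rng.standard_normal(grid.shape)
            stack.add_layer(spec["name"], arr)
        self._stack = stack
        aio.write_stack(self.run_dir / "landscape", stack)

        occ_dir = self.run_dir / "occurrences"
        occ_dir.mkdir(exist_ok=True)
        truth_dir = self.run_dir / "truth"
        truth_dir.mkdir(exist_ok=True)
        species_meta = {}
        for sp in self._species_cfgs():
            vs = self._virtual_species(sp)
            self._species[sp["name"]] = vs
            occ = sample_occurrences(
                vs, stack, n=int(sp.get("n_occurrences", 250)),
                seed=child_seed(self.seed, f"occ:{sp['name']}"))
            raw = occ.presences
            if self.cfg["contaminate"]:
                raw = pd.concat([raw, self._bad_records(sp["name"], stack)],
                                ignore_index=True)
            aio.write_occurrences(self._occ_csv(sp["name"], "raw"), raw)
            aio.write_ascii_grid(truth_dir / f"{sp['name']}_suitability.asc",
                                 true_suitability(vs, stack), grid)
            species_meta[sp["name"]] = {
                "group": sp.get("group", ""),
                "niche": {k: [float(m), float(s)] for k, (m, s) in vs.niche.items()},
                "prevalence_target": vs.prevalence_target,
            }
        (self.run_dir / "species.json").write_text(
            json.dumps(species_meta, indent=1, sort_keys=True))

        for spec in self._scenario_specs():
            futures = generate_future_stacks(stack, spec)
            for g, fut in enumerate(futures):
                aio.write_stack(
                    self.run_dir / "scenarios" / spec.name / f"gcm_{g:02d}", fut)
        self._log("simulate", species=len(self._species_cfgs()),
                  scenarios=len(self.cfg["scenarios"]))

    def _virtual_species(self, sp: dict) -> VirtualSpecies:
        stack = self._stack if self._stack is not None else aio.read_stack(
            self.run_dir / "landscape")
        sseed = child_seed(self.seed, f"species:{sp['name']}")
        layers = sp.get("niche_layers")
        if layers is None:
            rng = np.random.default_rng(sseed)
            candidates = [n for n in self.cfg["layers"]]
            temps = [n for n in candidates if is_temperature_like(n)]
            others = [n for n in candidates if not is_temperature_like(n)]
            layers = []
            if temps:
                layers.append(temps[rng.integers(0, len(temps))])
            extra = [n for n in candidates if n not in layers]
            extra = [extra[i] for i in rng.permutation(len(extra))]
            layers += extra[:max(0, 3 - len(layers))]
        return make_virtual_species(stack, layers, seed=sseed,
                                    prevalence_target=float(sp.get("prevalence", 0.15)),
                                    name=sp["name"])

    def _bad_records(self, name: str, stack: PredictorStack) -> pd.DataFrame:
        """Deterministic defective records for the cleaning stage to reject."""
        g = stack.grid
        rows = [
            {"species": name, "lon": np.nan, "lat": np.nan, "year": 2000, "source": "bad"},
            {"species": name, "lon": g.x_min + 0.1 * g.resolution, "lat": np.nan,
             "year": 2000, "source": "bad"},
            {"species": name, "lon": 540.0, "lat": 10.0, "year": 2000, "source": "bad"},
            {"species": name, "lon": g.x_max + 5.0, "lat": g.y_min + 0.5 * g.resolution,
             "year": 2000, "source": "bad"},
            {"species": name, "lon": g.x_min + 0.5 * g.resolution,
             "lat": g.y_min + 0.5 * g.resolution, "year": 1950, "source": "bad"},
        ]
        off = np.nonzero(~stack.mask)
        if len(off[0]):
            lon, lat = g.cell_center(off[0][0], off[1][0])
            rows.append({"species": name, "lon": float(lon), "lat": float(lat),
                         "year": 2000, "source": "bad"})
        return pd.DataFrame(rows)

    def stage_clean(self) -> None:
        stack = self.stack()
        rejections = {}
        for sp in self._species_cfgs():
            raw = aio.read_occurrences(self._occ_csv(sp["name"], "raw"))
            occ, counts = clean_occurrences(raw, stack, min_year=self.cfg["min_year"])
            aio.write_occurrences(self._occ_csv(sp["name"], "clean"), occ.presences)
            rejections[sp["name"]] = counts
        (self.run_dir / "occurrences" / "rejections.json").write_text(
            json.dumps(rejections, indent=1, sort_keys=True))
        self._log("clean", species=len(rejections))

    def stage_thin(self) -> None:
        stack = self.stack()
        cell = self.cfg["thin_cell"] or stack.grid.resolution
        kept = {}
        for sp in self._species_cfgs():
            occ = self._read_occ(sp["name"], "clean")
            thinned = thin_systematic(occ, cell, grid=stack.grid,
                                      seed=child_seed(self.seed, f"thin:{sp['name']}"))
            aio.write_occurrences(self._occ_csv(sp["name"], "thin"), thinned.presences)
            kept[sp["name"]] = thinned.n_presences
        self._log("thin", cell_size=cell, kept=kept)

    def stage_pseudoabs(self) -> None:
        stack = self.stack()
        for sp in self._species_cfgs():
            occ = self._read_occ(sp["name"], "thin")
            occ = sample_pseudo_absences(
                occ, stack, n=int(self.cfg["n_pseudo_absences"]),
                seed=child_seed(self.seed, f"pa:{sp['name']}"))
            occ.pseudo_absences.to_csv(self._occ_csv(sp["name"], "pa"), index=False)
        self._log("pseudoabs", n=self.cfg["n_pseudo_absences"])

    def stage_vif(self) -> None:
        stack = self.stack()
        report = select_predictors_vif(
            stack, threshold=self.cfg["vif_threshold"],
            sample=self.cfg["vif_sample"], seed=child_seed(self.seed, "vif"))
        report.to_json(self.run_dir / "vif_report.json")
        self._log("vif", retained=report.retained)

    def _retained_predictors(self) -> list[str]:
        path = self.run_dir / "vif_report.json"
        if not path.exists():
            self.stage_vif()
        return json.loads(path.read_text())["retained"]

    def _learners(self):
        registry = default_learners()
        wanted = self.cfg["learners"]
        if wanted is None:
            return registry
        by_name = {l.name: l for l in registry}
        return [by_name[n] for n in wanted]

    def stage_fit(self) -> None:
        stack = self.stack()
        predictors = self._retained_predictors()
        models_dir = self.run_dir / "models"
        models_dir.mkdir(exist_ok=True)
        for sp in self._species_cfgs():
            name = sp["name"]
            occ = self._read_occ(name, "thin")
            occ.pseudo_absences = pd.read_csv(self._occ_csv(name, "pa"))
            calib = fit_ensemble(
                occ, stack, predictors, learners=self._learners(),
                k=int(self.cfg["k_folds"]), weight_cutoff=self.cfg["weight_cutoff"],
                seed=child_seed(self.seed, f"fit:{name}"))
            self._calibrations[name] = calib
            (models_dir / f"{name}_calibration.json").write_text(
                json.dumps(calib.summary(), indent=1, sort_keys=True))
            suit = predict_consensus(calib, stack)
            aio.write_ascii_grid(models_dir / f"{name}_suitability.asc", suit, stack.grid)
            binary = binarize(suit, calib.threshold)
            self._baseline_binary[name] = binary
            aio.write_ascii_grid(models_dir / f"{name}_baseline_binary.asc",
                                 binary, stack.grid)
        self._log("fit", species=list(self._calibrations),
                  predictors=predictors)

    def _ensure_fitted(self) -> None:
        if not self._calibrations:
            self.stage_fit()

    def stage_project(self) -> None:
        """Project onto every GCM stack and integrate the votes per scenario."""
        self._ensure_fitted()
        proj_dir = self.run_dir / "projections"
        proj_dir.mkdir(exist_ok=True)
        grid = self.stack().grid
        for spec in self._scenario_specs():
            gcm_dirs = sorted((self.run_dir / "scenarios" / spec.name).glob("gcm_*"))
            gcm_stacks = [aio.read_stack(d) for d in gcm_dirs]
            for sp_name, calib in self._calibrations.items():
                pset = project_and_integrate(calib, gcm_stacks, spec.name,
                                             agreement=self.cfg["agreement"])
                self._integrated[(sp_name, spec.name)] = pset.integrated
                base = proj_dir / f"{sp_name}_{spec.name}"
                aio.write_ascii_grid(f"{base}_integrated.asc", pset.integrated, grid)
                aio.write_ascii_grid(f"{base}_uncertain.asc",
                                     pset.uncertain.astype(float), grid)
                if self.cfg["write_gcm_maps"]:
                    for g, m in enumerate(pset.gcm_maps):
                        aio.write_ascii_grid(f"{base}_gcm{g:02d}.asc", m, grid)
        self._log("project", pairs=len(self._integrated))

    # integration happens inside stage_project (votes are integrated per
    # scenario as soon as the member maps exist); the alias keeps the
    # stage list explicit for the CLI.
    stage_integrate = stage_project

    def _ensure_projected(self) -> None:
        if not self._integrated:
            self.stage_project()

    def stage_analyze(self) -> None:
        """Change, replacement and portfolio summaries."""
        self._ensure_fitted()
        self._ensure_projected()
        stack = self.stack()
        elev = stack.layers["elevation"]
        out = self.run_dir / "analysis"
        out.mkdir(exist_ok=True)
        groups = {sp["name"]: sp.get("group", "") for sp in self._species_cfgs()}
        crops = list(self.cfg["crops"])
        scen_names = [s["name"] for s in self.cfg["scenarios"]]

        area_rows, band_frames = [], []
        per_scenario_changes: dict[str, dict[str, ch.ChangeMap]] = {s: {} for s in scen_names}
        for (sp_name, sc_name), fut in sorted(self._integrated.items()):
            base = self._baseline_binary[sp_name]
            cm = ch.classify_change(base, fut, baseline_id=sp_name,
                                    future_id=f"{sp_name}:{sc_name}")
            per_scenario_changes[sc_name][sp_name] = cm
            aio.write_ascii_grid(out / f"{sp_name}_{sc_name}_change.asc",
                                 cm.categories.astype(float), stack.grid)
            pct = ch.area_change_percent(cm)
            area_rows.append({"species": sp_name, "scenario": sc_name, **pct})
            prof = ch.altitudinal_profile(cm, elev,
                                          bin_width=self.cfg["elevation_bin_width"])
            bands = prof.bands.copy()
            bands.insert(0, "scenario", sc_name)
            bands.insert(0, "species", sp_name)
            band_frames.append(bands)
        pd.DataFrame(area_rows).to_csv(out / "area_change.csv", index=False)
        pd.concat(band_frames, ignore_index=True).to_csv(
            out / "altitude_bands.csv", index=False)

        if len(crops) >= 2:
            a, b = crops[0], crops[1]
            rep_rows = []
            for sc in scen_names:
                rm = ch.replacement_analysis(
                    per_scenario_changes[sc][a],
                    self._integrated[(b, sc)], elevation=elev)
                rep_rows.append({"scenario": sc, "crop_a": a, "crop_b": b,
                                 "replaceable_pct": rm.replaceable_fraction})
                bf = rm.band_fractions.copy()
                bf.insert(0, "scenario", sc)
                bf.to_csv(out / f"replacement_bands_{sc}.csv", index=False)
            pd.DataFrame(rep_rows).to_csv(out / "replacement.csv", index=False)

        trees = [n for n in groups if n not in crops]
        if trees and crops:
            pcfg = self.cfg["portfolio"]
            rows = []
            for sc in scen_names:
                crop_cm = per_scenario_changes[sc][crops[0]].categories
                crop_area = np.where(
                    crop_cm == ch.INVALID, np.nan,
                    np.isin(crop_cm, [ch.REMAIN, ch.LOSS, ch.GAIN]).astype(float))
                pm = ch.portfolio_richness(
                    {t: self._integrated[(t, sc)] for t in trees},
                    groups, crop_area,
                    rich_total=pcfg["rich_total"],
                    rich_per_group=pcfg["rich_per_group"],
                    low_cutoff=pcfg["low_cutoff"])
                rows.append({"scenario": sc, "crop": crops[0], **pm.fractions})
            pd.DataFrame(rows).to_csv(out / "portfolio.csv", index=False)

        tbl_frames, cnt_frames = [], []
        for sc in scen_names:
            tbl, cnts = ch.species_area_change_table(per_scenario_changes[sc], groups)
            tbl.insert(0, "scenario", sc)
            cnts.insert(0, "scenario", sc)
            tbl_frames.append(tbl)
            cnt_frames.append(cnts)
        pd.concat(tbl_frames, ignore_index=True).to_csv(
            out / "species_table.csv", index=False)
        pd.concat(cnt_frames, ignore_index=True).to_csv(
            out / "group_counts.csv", index=False)
        self._log("analyze", species=len(groups), scenarios=len(scen_names))

    def run_all(self) -> Path:
        """Execute every stage in order and write the run manifest."""
        self.stage_simulate()
        self.stage_clean()
        self.stage_thin()
        self.stage_pseudoabs()
        self.stage_vif()
        self.stage_fit()
        self.stage_project()
        self.stage_analyze()
        self.write_manifest()
        return self.run_dir

    def write_manifest(self) -> None:
        files = sorted(p for p in self.run_dir.rglob("*")
                       if p.is_file() and p.name not in {"manifest.json", "log.jsonl"})
        manifest = {
            "config_hash": self.hash,
            "seed": self.seed,
            "files": {str(p.relative_to(self.run_dir)): aio.sha256_of(p)
                      for p in files},
        }
        (self.run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))


def demo_config(seed: int) -> dict:
    """Small synthetic study: 3 virtual species, 2 scenarios x 5 pseudo-GCMs.

    Portfolio thresholds are scaled to the single demo tree species; the
    library defaults (30/10/3) apply to full-scale studies.
    """
    return validate_config({
        "seed": int(seed),
        "grid": {"n_rows": 48, "n_cols": 48, "x_min": -100.0, "y_max": 20.0,
                 "resolution": 0.05},
        "layers": ["bio02", "bio08", "bio13", "bio14", "bio19"],
        "add_collinear": [{"name": "bio07", "parents": ["bio02", "bio08"],
                           "weights": [0.7, 0.3], "noise": 0.05}],
        "species": [
            {"name": "coffea_like", "group": "crop", "n_occurrences": 250,
             "prevalence": 0.12, "niche_layers": ["bio08", "bio13", "bio14"]},
            {"name": "theobroma_like", "group": "crop", "n_occurrences": 220,
             "prevalence": 0.18, "niche_layers": ["bio08", "bio19"]},
            {"name": "inga_like", "group": "nfixing", "n_occurrences": 200,
             "prevalence": 0.2, "niche_layers": ["bio02", "bio13"]},
        ],
        "crops": ["coffea_like", "theobroma_like"],
        "scenarios": [
            {"name": "rcp45like", "gcm_count": 5,
             "mean_shift": {"bio02": 0.3, "bio08": 0.5, "bio14": -0.2},
             "gcm_spread": {"bio02": 0.1, "bio08": 0.15, "bio13": 0.1, "bio14": 0.1}},
            {"name": "rcp85like", "gcm_count": 5,
             "mean_shift": {"bio02": 0.6, "bio08": 1.0, "bio14": -0.4},
             "gcm_spread": {"bio02": 0.1, "bio08": 0.15, "bio13": 0.1, "bio14": 0.1}},
        ],
        "n_pseudo_absences": 1000,
        "portfolio": {"rich_total": 0, "rich_per_group": 1, "low_cutoff": 0},
    })


def make_demo_fixtures(seed: int, out_dir) -> Path:
    """Write the demo config plus its simulated inputs and a checksum manifest."""
    out_dir = Path(out_dir)
    cfg = demo_config(seed)
    run = PipelineRun(cfg, out_dir)
    run.stage_simulate()
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    run.write_manifest()
    return out_dir
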