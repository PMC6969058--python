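"""End-to-end pipeline: config in, staged artifacts on disk out.

The run config (YAML) supplies either a ``simulate`` block (synthetic study)
or an ``inputs`` block (paths to trait/range/SST/tree/IUCN files), plus
method options and erosion settings.  Stages write CSV artifacts into the
output directory and a manifest records the config hash and seed; a stage
whose outputs already exist under a matching manifest is skipped, so e.g.
re-running erosion does not recompute exposure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .erosion import ErosionScenario, compare_curves, run_erosion
from .exposure import ExposureScorer, ensemble_delta
from .functional import GowerPCoA
from .grids import GridField, RangeMatrix, read_grid
from .phylo import ed_over_trees
from .schema import TraitSchema, default_schema
from .sensitivity import SensitivityScorer, breakpoint_robustness
from .synth import SynthConfig, SyntheticStudy, simulate
from .trees import read_trees, write_trees
from .vulnerability import (assemblage_map, compute_vulnerability,
                            latitudinal_profile, rank_species)

log = logging.getLogger(__name__)

STAGES = ("simulate", "sensitivity", "exposure", "vulnerability",
          "diversity", "erosion")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} is not a mapping")
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise PipelineError(
            "config", "exactly one of 'simulate' or 'inputs' must be present")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _scenario_keys(cfg: dict) -> list[tuple[str, str]]:
    opts = cfg.get("options", {})
    keys = opts.get("scenarios")
    if keys:
        return [tuple(k.split("/")) for k in keys]
    return list(SynthConfig().scenario_scales)


class Runner:
    """Load inputs once, run stages on demand, write artifacts."""

    def __init__(self, cfg: dict, out_dir: str | Path, seed: int | None = None):
        self.cfg = cfg
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        if seed is not None:
            self.cfg.setdefault("simulate", {})
            if "simulate" in cfg and isinstance(cfg["simulate"], dict):
                cfg["simulate"]["seed"] = seed
        self.opts = cfg.get("options", {})
        self.hash = config_hash(cfg)
        self._study: SyntheticStudy | None = None
        self._loaded: dict = {}

    # -- manifest / caching ----------------------------------------------

    def _manifest_path(self, stage: str) -> Path:
        return self.out / f".manifest_{stage}.json"

    def _fresh(self, stage: str, outputs: list[Path]) -> bool:
        mp = self._manifest_path(stage)
        if not mp.exists() or not all(p.exists() for p in outputs):
            return False
        try:
            return json.loads(mp.read_text()).get("config_hash") == self.hash
        except json.JSONDecodeError:
            return False

    def _stamp(self, stage: str) -> None:
        from importlib.metadata import version, PackageNotFoundError
        try:
            ver = version("thermovuln")
        except PackageNotFoundError:
            ver = "unknown"
        self._manifest_path(stage).write_text(json.dumps(
            {"config_hash": self.hash, "stage": stage, "version": ver,
             "seed": self.cfg.get("simulate", {}).get("seed")}, indent=2))

    # -- input assembly ---------------------------------------------------

    def _synth_config(self) -> SynthConfig:
        block = dict(self.cfg.get("simulate") or {})
        known = {f.name for f in dc_fields(SynthConfig)}
        unknown = sorted(set(block) - known)
        if unknown:
            raise PipelineError("simulate", f"unknown simulate keys: {unknown}")
        if "iucn_counts" in block:
            block["iucn_counts"] = dict(block["iucn_counts"])
        return SynthConfig(**block)

    def study(self) -> SyntheticStudy:
        if "simulate" not in self.cfg:
            raise PipelineError("simulate", "config has no simulate block")
        if self._study is None:
            self._study = simulate(self._synth_config())
        return self._study

    def _load(self, role: str):
        """Load one data role from the inputs block (real-data mode)."""
        if role in self._loaded:
            return self._loaded[role]
        inputs = self.cfg.get("inputs")
        if inputs is None:
            raise PipelineError("inputs", "config has no inputs block")
        try:
            if role == "schema":
                path = inputs.get("schema")
                val = TraitSchema.from_yaml(path) if path else default_schema()
            elif role == "traits":
                val = tio.read_trait_table(inputs["traits"], self._load("schema"))
            elif role == "ranges":
                val = RangeMatrix.read_csv(inputs["ranges"])
            elif role == "iucn":
                val = tio.read_iucn(inputs["iucn"])
            elif role == "trees":
                val = read_trees(inputs["trees"])
            elif role == "baselines":
                val = [read_grid(p) for p in inputs["baselines"]]
            elif role == "futures":
                val = {tuple(k.split("/")): [read_grid(p) for p in paths]
                       for k, paths in inputs["futures"].items()}
            else:
                raise KeyError(role)
        except FileNotFoundError as exc:
            raise PipelineError(role, f"input file not found: {exc}") from exc
        except KeyError as exc:
            raise PipelineError(role, f"missing input entry: {exc}") from exc
        self._loaded[role] = val
        return val

    def _get(self, role: str):
        if "simulate" in self.cfg:
            st = self.study()
            return {"schema": st.schema, "traits": st.traits,
                    "ranges": st.ranges, "iucn": st.iucn, "trees": st.trees,
                    "baselines": st.baselines, "futures": st.futures,
                    "grid": st.grid}[role]
        if role == "grid":
            return self._load("baselines")[0]
        return self._load(role)

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> None:
        outputs = [self.out / n for n in
                   ("traits.csv", "ranges.csv", "iucn.csv", "trees.nwk")]
        if self._fresh("simulate", outputs):
            log.info("simulate: outputs up to date, skipping")
            return
        st = self.study()
        tio.write_trait_table(st.traits, self.out / "traits.csv")
        st.ranges.write_csv(self.out / "ranges.csv")
        tio.write_iucn(st.iucn, self.out / "iucn.csv")
        write_trees(st.trees, self.out / "trees.nwk")
        st.schema.to_yaml(self.out / "schema.yaml")
        self._stamp("simulate")

    def stage_sensitivity(self) -> pd.DataFrame:
        out_path = self.out / "sensitivity.csv"
        schema, traits = self._get("schema"), self._get("traits")
        scorer = SensitivityScorer(schema)
        table = scorer.score_table(traits)
        table.to_csv(out_path)
        breakpoint_robustness(traits, schema).to_csv(
            self.out / "sensitivity_robustness.csv", index=False)
        self._stamp("sensitivity")
        return table

    def _deltas(self) -> dict[tuple[str, str], GridField]:
        baselines = self._get("baselines")
        futures = self._get("futures")
        return {key: ensemble_delta(baselines, members,
                                    scenario=key[0], period=key[1])
                for key, members in futures.items()}

    def stage_exposure(self) -> dict[tuple[str, str], pd.DataFrame]:
        ranges = self._get("ranges")
        scheme = self.opts.get("scheme", "tertile")
        results = {}
        frames = []
        for key, delta in self._deltas().items():
            scorer = ExposureScorer(scheme=scheme).fit(delta)
            table = scorer.transform(ranges)
            results[key] = table
            delta.write_csv(self.out / f"delta_{key[0]}_{key[1]}.csv")
            tagged = table.reset_index()
            tagged.insert(1, "scenario", key[0])
            tagged.insert(2, "period", key[1])
            frames.append(tagged)
        pd.concat(frames, ignore_index=True).to_csv(
            self.out / "exposure.csv", index=False)
        self._stamp("exposure")
        return results

    def stage_vulnerability(self) -> dict[tuple[str, str], pd.DataFrame]:
        sens = self.stage_sensitivity()
        expo = self.stage_exposure()
        ranges, grid = self._get("ranges"), self._get("grid")
        results = {}
        frames = []
        for key, table in expo.items():
            V = compute_vulnerability(sens["S"], table["P"])
            ranked = rank_species(V)
            results[key] = ranked
            amap = assemblage_map(ranges, V, grid)
            amap.write_csv(self.out / f"assemblage_V_{key[0]}_{key[1]}.csv")
            latitudinal_profile(amap).to_csv(
                self.out / f"lat_profile_{key[0]}_{key[1]}.csv", index=False)
            tagged = ranked.reset_index()
            tagged.insert(1, "scenario", key[0])
            tagged.insert(2, "period", key[1])
            frames.append(tagged)
        pd.concat(frames, ignore_index=True).to_csv(
            self.out / "vulnerability.csv", index=False)
        self._stamp("vulnerability")
        return results

    def stage_diversity(self) -> GowerPCoA:
        schema, traits, trees = (self._get("schema"), self._get("traits"),
                                 self._get("trees"))
        model = GowerPCoA(schema, n_axes=int(self.opts.get("n_axes", 4)))
        model.fit(traits)
        model.distances_.to_csv(self.out / "gower_distances.csv")
        model.space_.coordinates.to_csv(self.out / "pcoa_coordinates.csv")
        model.originality_.to_csv(self.out / "functional_originality.csv")
        ed = ed_over_trees(trees, self.opts.get("ed_scheme", "fair_proportion"))
        ed.to_csv(self.out / "evolutionary_distinctiveness.csv")
        self._stamp("diversity")
        return model

    def stage_erosion(self) -> dict[str, pd.DataFrame]:
        ecfg = self.cfg.get("erosion", {})
        key = tuple(ecfg.get("scenario_period", "rcp85/2070-2099").split("/"))
        n_rep = int(ecfg.get("n_replicates", 999))
        max_steps = ecfg.get("max_steps")
        seed = int(ecfg.get("seed", self.cfg.get("simulate", {}).get("seed", 0)))
        vmaps = self.stage_vulnerability()
        if key not in vmaps:
            raise PipelineError("erosion",
                                f"no vulnerability for scenario/period {key}")
        V = vmaps[key]
        iucn = self._get("iucn")
        model = self.stage_diversity()
        trees = self._get("trees")
        out = {}
        for metric in ("fric", "pd"):
            frames = []
            for kind, nrep in (("vulnerability", 1), ("random", n_rep),
                               ("iucn_vulnerability", 1), ("iucn_random", n_rep)):
                scen = ErosionScenario(kind=kind, n_replicates=nrep, seed=seed)
                curve = run_erosion(scen, metric, space=model.space_,
                                    trees=trees, V=V, iucn=iucn,
                                    max_steps=max_steps)
                frames.append(curve.to_dataframe())
            df = pd.concat(frames, ignore_index=True)
            df.to_csv(self.out / f"erosion_{metric}.csv", index=False)
            out[metric] = df
        self._stamp("erosion")
        return out

    def run(self, stage: str) -> None:
        try:
            if stage in ("simulate", "all") and "simulate" in self.cfg:
                self.stage_simulate()
            if stage == "sensitivity":
                self.stage_sensitivity()
            elif stage == "exposure":
                self.stage_exposure()
            elif stage == "vulnerability":
                self.stage_vulnerability()
            elif stage == "diversity":
                self.stage_diversity()
            elif stage == "erosion":
                self.stage_erosion()
            elif stage == "all":
                self.stage_erosion()  # pulls every upstream stage
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
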