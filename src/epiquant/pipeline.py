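"""Config-driven staged pipeline with resumable file intermediates.

Each stage reads its inputs from the working directory, writes outputs
under stable filenames, and appends a line to ``run.log``.  ``run_all``
executes the stages in dependency order, skipping a stage when its outputs
are newer than its inputs (unless forced), so a run directory is a
reproducible, inspectable artifact.  All randomness flows from the single
top-level ``seed``; stages derive sub-seeds from it by stage name.
"""

from __future__ import annotations

import copy
import time
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import io as eqio
from .assign import (
    AssignmentResult,
    assign_hull,
    assign_iterative,
    assign_mixed,
    assign_nearest_nucleus,
    assign_projection,
    compare_strategies,
)
from .core import ApicalCellMap, NucleiLabels, VoxelGrid
from .features import (
    build_cell_table,
    cluster_cells,
    measure_cytoplasmic_intensity,
    measure_nuclear_intensity,
    prefill_classification,
)
from .nuclei import filter_nuclei, segment_nuclei
from .pairing import pair_nuclei_to_cells, read_pairing, write_pairing
from .projection import estimate_cell_z, project_apical, segment_cells_2d
from .separation import separate_junction_nuclei
from .simulate import TissueParams, generate_tissue, write_bundle
from .spots import detect_spots

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "workdir": "epiquant_out",
    "spacing": [1.0, 0.2, 0.2],
    "simulate": {
        "enabled": True,
        "shape": [40, 256, 256],
        "n_cells": 50,
        "curvature": 0.0,
        "n_rna_channels": 1,
        "lambda_high": 30.0,
        "lambda_low": 3.0,
        "frac_high": 0.5,
        "gaussian_noise_sd": 20.0,
        "poisson_noise": False,
        "ihc_channel": True,
    },
    "input": {
        "stack": None,
        "channel_axis": 0,
        "junction_index": 0,
        "nuclei_index": 1,
        "ihc_index": None,
        "rna_indices": [2],
    },
    "project": {"method": "max", "smooth_sigma": 1.0, "z_range": None},
    "segment": {
        "seed_h": 40.0,
        "min_area": 5.0,
        "max_area": 500.0,
        "z_stat": "median",
    },
    "nuclei": {
        "radius": 2.3,
        "threshold": "auto",
        "min_volume": 20.0,
        "max_volume": 1000.0,
        "z_keep": None,
    },
    "pair": {"max_dist": 10.0, "wz": 0.25},
    "spots": {"radius_axial": 1.3, "radius_lateral": 0.43, "threshold": "auto"},
    "assign": {
        "strategies": ["projection", "nearest_nucleus", "mixed", "hull", "iterative"],
        "depth_cut": 5.0,
        "pad": 0.5,
        "k": 5,
        "max_iter": 10,
        "base": "mixed",
        "nucleus_distance": "surface",
    },
    "separate": {
        "channel": None,
        "nucleus_radius": 2.2,
        "junction_thickness": 0.6,
    },
    "features": {
        "cyto_depth": 4.0,
        "exclude_nucleus": False,
        "intensity_channels": ["ihc"],
        "classify_channel": "ihc",
        "classify_method": "otsu",
        "classify_threshold": None,
        "count_strategy": "mixed",
    },
    "cluster": {
        "enabled": True,
        "k": 2,
        "linkage": "ward",
        "features": ["area_um2", "count_rna0"],
    },
}

STAGE_ORDER = [
    "simulate",
    "project",
    "segment",
    "nuclei",
    "pair",
    "spots",
    "assign",
    "table",
    "cluster",
]


class ConfigError(ValueError):
    pass


def _check_keys(cfg: dict, ref: dict, path: str = "") -> None:
    for key, value in cfg.items():
        here = f"{path}.{key}" if path else key
        if key not in ref:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(ref[key], dict) and isinstance(value, dict):
            _check_keys(value, ref[key], here)


def merge_config(user: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if user:
        _check_keys(user, DEFAULT_CONFIG)

        def _merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    _merge(dst[k], v)
                else:
                    dst[k] = v

        _merge(cfg, user)
    return cfg


def load_config(path, overrides: list[str] | None = None) -> dict:
    """Load a YAML config, apply dotted key=value overrides, fill defaults."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    for item in overrides or []:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not key=value")
        key, _, raw = item.partition("=")
        value = yaml.safe_load(raw)
        node = user
        parts = key.split(".")
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value
    return merge_config(user)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


class Pipeline:
    """Stage runner bound to one config and working directory."""

    def __init__(self, config: dict):
        self.cfg = config
        self.workdir = Path(config["workdir"])
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.grid: VoxelGrid | None = None

    # ------------------------------------------------------------- helpers
    def _log(self, stage: str, seconds: float, note: str = "") -> None:
        from . import __version__

        with open(self.workdir / "run.log", "a") as fh:
            fh.write(
                f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {stage} "
                f"v{__version__} seed={self.cfg['seed']} "
                f"{seconds:.2f}s {note}\n"
            )

    def path(self, name: str) -> Path:
        return self.workdir / name

    def _spacing(self) -> tuple[float, float, float]:
        return tuple(self.cfg["spacing"])

    def rna_channel_names(self) -> list[str]:
        if self.cfg["simulate"]["enabled"]:
            return [f"rna{i}" for i in range(self.cfg["simulate"]["n_rna_channels"])]
        return [f"rna{i}" for i in range(len(self.cfg["input"]["rna_indices"]))]

    def load_channel(self, name: str):
        """Load a named channel (junction / nuclei / ihc / rna<i>)."""
        if self.cfg["simulate"]["enabled"]:
            p = self.path(f"channel_{name}.tif")
            if not p.exists():
                raise FileNotFoundError(
                    f"missing {p}: run the 'simulate' stage first"
                )
            return eqio.read_stack(p, spacing=self._spacing())[0]
        inp = self.cfg["input"]
        if inp["stack"] is None:
            raise ConfigError("input.stack is not set and simulation is disabled")
        channels = eqio.read_stack(
            inp["stack"], channel_axis=inp["channel_axis"], spacing=self._spacing()
        )
        if name == "junction":
            idx = inp["junction_index"]
        elif name == "nuclei":
            idx = inp["nuclei_index"]
        elif name == "ihc":
            idx = inp["ihc_index"]
        elif name.startswith("rna"):
            idx = inp["rna_indices"][int(name[3:])]
        else:
            raise ConfigError(f"unknown channel {name!r}")
        if idx is None:
            raise ConfigError(f"no channel index configured for {name!r}")
        ch = channels[idx]
        ch.channel_name = name
        return ch

    def load_cells(self) -> ApicalCellMap:
        lp, zp = self.path("cells.tif"), self.path("cells_z.csv")
        if not (lp.exists() and zp.exists()):
            raise FileNotFoundError("missing cell map: run the 'segment' stage first")
        grid = self._grid_from_any_channel()
        return eqio.read_apical_map(lp, zp, grid)

    def load_nuclei(self) -> NucleiLabels:
        p = self.path("nuclei.tif")
        if not p.exists():
            raise FileNotFoundError("missing nuclei: run the 'nuclei' stage first")
        grid = self._grid_from_any_channel()
        labels = eqio.read_labels(p)
        return NucleiLabels.from_labels(labels, grid)

    def _grid_from_any_channel(self) -> VoxelGrid:
        if self.grid is None:
            self.grid = self.load_channel("junction").grid
        return self.grid

    def _fresh(self, outputs: list[Path], inputs: list[Path]) -> bool:
        if not all(p.exists() for p in outputs):
            return False
        if not inputs:
            return True
        newest_in = max(p.stat().st_mtime for p in inputs if p.exists())
        return min(p.stat().st_mtime for p in outputs) >= newest_in

    # -------------------------------------------------------------- stages
    def run_simulate(self) -> None:
        t0 = time.time()
        sim = self.cfg["simulate"]
        params = TissueParams(
            shape=tuple(sim["shape"]),
            spacing=self._spacing(),
            n_cells=sim["n_cells"],
            curvature=sim["curvature"],
            n_rna_channels=sim["n_rna_channels"],
            lambda_high=sim["lambda_high"],
            lambda_low=sim["lambda_low"],
            frac_high=sim["frac_high"],
            gaussian_noise_sd=sim["gaussian_noise_sd"],
            poisson_noise=sim["poisson_noise"],
            ihc_channel=sim["ihc_channel"],
            seed=stage_seed(self.cfg["seed"], "simulate"),
        )
        bundle = generate_tissue(params)
        write_bundle(bundle, self.workdir)
        self._log("simulate", time.time() - t0, f"n_cells={params.n_cells}")

    def run_project(self) -> None:
        t0 = time.time()
        junction = self.load_channel("junction")
        pj = self.cfg["project"]
        zref = project_apical(
            junction,
            method=pj["method"],
            smooth_sigma=pj["smooth_sigma"],
            z_range=tuple(pj["z_range"]) if pj["z_range"] else None,
        )
        eqio.write_labels(
            np.round(zref.zmap).astype(np.int32), self.path("zmap.tif")
        )
        np.save(self.path("zmap.npy"), zref.zmap)
        np.save(self.path("projection.npy"), zref.projection)
        self._log("project", time.time() - t0)

    def _load_zref(self):
        from .core import ZReferenceMap

        zp, pp = self.path("zmap.npy"), self.path("projection.npy")
        if not (zp.exists() and pp.exists()):
            raise FileNotFoundError("missing projection: run the 'project' stage first")
        grid = self._grid_from_any_channel()
        return ZReferenceMap(np.load(zp), np.load(pp), grid)

    def run_segment(self) -> None:
        t0 = time.time()
        zref = self._load_zref()
        sg = self.cfg["segment"]
        labels = segment_cells_2d(
            zref, sg["seed_h"], sg["min_area"], sg["max_area"]
        )
        cells = estimate_cell_z(labels, zref, stat=sg["z_stat"])
        eqio.write_labels(cells.labels2d, self.path("cells.tif"))
        eqio.write_cell_z(cells.cell_z, self.path("cells_z.csv"))
        self._log("segment", time.time() - t0, f"n_cells={len(cells.labels)}")

    def run_nuclei(self) -> None:
        t0 = time.time()
        nuc_cfg = self.cfg["nuclei"]
        channel = self.load_channel("nuclei")
        nuclei = segment_nuclei(channel, nuc_cfg["radius"], nuc_cfg["threshold"])
        nuclei = filter_nuclei(
            nuclei,
            nuc_cfg["min_volume"],
            nuc_cfg["max_volume"],
            tuple(nuc_cfg["z_keep"]) if nuc_cfg["z_keep"] else None,
        )
        eqio.write_labels(nuclei.labels3d, self.path("nuclei.tif"))
        nuclei.props.to_csv(
            self.path("nuclei_props.csv"), index=False, float_format="%.6g"
        )
        self._log("nuclei", time.time() - t0, f"n={len(nuclei.props)}")

    def run_pair(self) -> None:
        t0 = time.time()
        cells = self.load_cells()
        nuclei = self.load_nuclei()
        pr = self.cfg["pair"]
        pairing = pair_nuclei_to_cells(cells, nuclei, pr["max_dist"], pr["wz"])
        write_pairing(pairing, self.path("pairing.csv"))
        self._log("pair", time.time() - t0, f"pairs={len(pairing.pairs)}")

    def run_spots(self) -> None:
        t0 = time.time()
        sp = self.cfg["spots"]
        for name in self.rna_channel_names():
            channel = self.load_channel(name)
            spots = detect_spots(
                channel, (sp["radius_axial"], sp["radius_lateral"]), sp["threshold"]
            )
            eqio.write_spots(spots, self.path(f"spots_{name}.csv"))
        self._log("spots", time.time() - t0)

    def run_separate(self) -> None:
        t0 = time.time()
        sep = self.cfg["separate"]
        name = sep["channel"]
        if name is None:
            raise ConfigError("separate.channel is not set")
        mixed = self.load_channel(name)
        junctions, nuclei = separate_junction_nuclei(
            mixed, sep["nucleus_radius"], sep["junction_thickness"]
        )
        eqio.write_volume(junctions, self.path(f"separated_{name}_junctions.tif"))
        eqio.write_volume(nuclei, self.path(f"separated_{name}_nuclei.tif"))
        self._log("separate", time.time() - t0)

    def assign_one(
        self, spots, cells, nuclei, pairing, strategy: str
    ) -> AssignmentResult:
        ag = self.cfg["assign"]
        if strategy == "projection":
            return assign_projection(spots, cells)
        if strategy == "nearest_nucleus":
            return assign_nearest_nucleus(
                spots, nuclei, pairing, ag["nucleus_distance"]
            )
        if strategy == "mixed":
            return assign_mixed(
                spots, cells, nuclei, pairing, ag["depth_cut"], ag["nucleus_distance"]
            )
        if strategy == "hull":
            return assign_hull(spots, cells, nuclei, pairing, ag["pad"])
        if strategy == "iterative":
            base = self.assign_one(spots, cells, nuclei, pairing, ag["base"])
            res = assign_iterative(base, self._spacing(), ag["k"], ag["max_iter"])
            res.strategy = "iterative"
            return res
        raise ConfigError(f"unknown assignment strategy {strategy!r}")

    def run_assign(self) -> None:
        t0 = time.time()
        cells = self.load_cells()
        nuclei = self.load_nuclei()
        pairing = read_pairing(self.path("pairing.csv"))
        for name in self.rna_channel_names():
            sp = self.path(f"spots_{name}.csv")
            if not sp.exists():
                raise FileNotFoundError(f"missing {sp}: run the 'spots' stage first")
            spots = eqio.read_spots(sp, channel=name)
            results = []
            for strategy in self.cfg["assign"]["strategies"]:
                res = self.assign_one(spots, cells, nuclei, pairing, strategy)
                eqio.write_spots(
                    res.spots, self.path(f"spots_{name}_{strategy}.csv")
                )
                results.append(res)
            if len(results) > 1:
                compare_strategies(results).to_csv(
                    self.path(f"comparison_{name}.csv"), float_format="%.6g"
                )
        self._log("assign", time.time() - t0)

    def run_table(self) -> None:
        t0 = time.time()
        cells = self.load_cells()
        nuclei = self.load_nuclei()
        pairing = read_pairing(self.path("pairing.csv"))
        ft = self.cfg["features"]
        assignments = []
        for name in self.rna_channel_names():
            p = self.path(f"spots_{name}_{ft['count_strategy']}.csv")
            if not p.exists():
                raise FileNotFoundError(f"missing {p}: run the 'assign' stage first")
            assignments.append(
                AssignmentResult(eqio.read_spots(p, channel=name), ft["count_strategy"])
            )
        cyto = {}
        nuclear = {}
        for name in ft["intensity_channels"]:
            try:
                channel = self.load_channel(name)
            except (ConfigError, FileNotFoundError):
                continue
            cyto[name] = measure_cytoplasmic_intensity(
                channel,
                cells,
                ft["cyto_depth"],
                nuclei if ft["exclude_nucleus"] else None,
            )
            nuclear[name] = measure_nuclear_intensity(channel, nuclei)
        classes = {}
        if ft["classify_channel"] and ft["classify_channel"] in cyto:
            classes[ft["classify_channel"]] = prefill_classification(
                cyto[ft["classify_channel"]]["mean"].dropna(),
                method=ft["classify_method"],
                threshold=ft["classify_threshold"],
                name=ft["classify_channel"],
            )
        table = build_cell_table(
            cells, nuclei, pairing, assignments, cyto, nuclear, classes
        )
        eqio.write_cell_table(table, self.path("cell_table.csv"))
        self._log("table", time.time() - t0, f"rows={len(table)}")

    def run_cluster(self) -> None:
        t0 = time.time()
        cl = self.cfg["cluster"]
        if not cl["enabled"]:
            return
        p = self.path("cell_table.csv")
        if not p.exists():
            raise FileNotFoundError("missing cell_table.csv: run the 'table' stage first")
        table = eqio.read_cell_table(p)
        feats = [f for f in cl["features"] if f in table.columns]
        if feats:
            table["cluster"] = cluster_cells(table, feats, cl["k"], cl["linkage"])
            eqio.write_cell_table(table, p)
        self._log("cluster", time.time() - t0)

    # ---------------------------------------------------------- run-all
    STAGE_FILES = {
        "simulate": ([], ["channel_junction.tif"]),
        "project": (["channel_junction.tif"], ["zmap.npy", "projection.npy"]),
        "segment": (["zmap.npy", "projection.npy"], ["cells.tif", "cells_z.csv"]),
        "nuclei": (["channel_nuclei.tif"], ["nuclei.tif", "nuclei_props.csv"]),
        "pair": (["cells.tif", "nuclei.tif"], ["pairing.csv"]),
        "spots": (["channel_rna0.tif"], ["spots_rna0.csv"]),
        "assign": (["spots_rna0.csv", "pairing.csv"], []),
        "table": (["pairing.csv"], ["cell_table.csv"]),
        "cluster": (["cell_table.csv"], []),
    }

    def run_stage(self, name: str) -> None:
        getattr(self, f"run_{name}")()

    def run_all(self, force: bool = False) -> None:
        for name in STAGE_ORDER:
            if name == "simulate" and not self.cfg["simulate"]["enabled"]:
                continue
            ins, outs = self.STAGE_FILES.get(name, ([], []))
            ins_p = [self.path(p) for p in ins]
            outs_p = [self.path(p) for p in outs]
            if not force and outs_p and self._fresh(outs_p, ins_p):
                self._log(name, 0.0, "skipped (fresh)")
                continue
            self.run_stage(name)
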