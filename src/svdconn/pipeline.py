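"""End-to-end orchestration: synthetic data -> tracking -> connectome ->
metrics -> edgewise NBS -> cohort statistics, from a single YAML config.

Each stage writes its outputs in the standard on-disk format so any stage
can be re-run or inspected by the corresponding CLI command; a master seed
deterministically derives each stage's seed (hash of master seed + stage
name), so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sio
from .connectome import EdgeWeightConfig, build_connectome
from .graph_metrics import compute_metrics
from .nbs import Contrast, DesignMatrix, nbs_test
from .stats import (
    ancova_type2,
    correlate,
    group_contingency,
    log_transform,
    mediation_path,
    multiple_regression_standardized,
    posthoc_tukey,
)
from .synthetic import (
    ArcBundle,
    CohortSpec,
    StraightBundle,
    TensorFieldSpec,
    make_parcellation,
    make_tensor_field,
    simulate_cohort,
)
from .tractography import TrackingConfig, track

__all__ = ["PipelineConfig", "run", "derive_seed", "DEFAULT_CONFIG"]

STAGES = ("tensors", "tracking", "connectome", "cohort", "metrics", "nbs", "stats")

DEFAULT_CONFIG: dict = {
    "out_dir": "svdconn_out",
    "master_seed": 0,
    "stages": {s: True for s in STAGES},
    "tensor_field": {
        "grid_dims": [30, 12, 12],
        "voxel_size": [1.0, 1.0, 1.0],
        "background_fa": 0.05,
        "bundles": [
            {"geometry": "straight", "start": [1.0, 5.5, 5.5],
             "direction": [1.0, 0.0, 0.0], "length": 27.0, "radius": 2.0}
        ],
    },
    "parcellation": {"n_per_hemisphere": 1},
    "tracking": {"seed_spacing": 1.0, "fa_threshold": 0.2,
                 "angle_threshold_deg": 45.0, "step_mm": 0.5},
    "edge_weight": {"seeds_per_mm": 1.0, "threshold": 1.0},
    "cohort": {"n_participants": 60, "parcellation_nodes": 30,
               "apathy_edge_set": [[0, 1], [1, 2], [2, 3], [3, 4]]},
    "nbs": {"predictor": "AES", "covariates": ["CESD"], "t_threshold": 3.1,
            "n_permutations": 1000, "alpha": 0.025, "direction": "negative"},
    "stats": {"covariates": ["CESD", "MMSE", "education"]},
}


def derive_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Study configuration; any section omitted falls back to the default."""

    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, val in self.settings.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        self.settings = merged
        unknown = set(self.settings["stages"]) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(sio.load_yaml(path) or {})

    def __getitem__(self, key):
        return self.settings[key]


def _build_bundles(bundle_cfgs: list) -> list:
    bundles = []
    for cfg in bundle_cfgs:
        cfg = dict(cfg)
        geom = cfg.pop("geometry", "straight")
        if geom == "straight":
            bundles.append(StraightBundle(**cfg))
        elif geom == "arc":
            bundles.append(ArcBundle(**cfg))
        else:
            raise ValueError(f"unknown bundle geometry: {geom}")
    return bundles


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config["out_dir"])
    stages = config["stages"]
    master = int(config["master_seed"])
    manifest: dict = {"master_seed": master, "stages": {}, "outputs": {}}

    def record(stage: str, t0: float, **outputs) -> None:
        manifest["stages"][stage] = {
            "seed": derive_seed(master, stage),
            "wall_time_s": round(time.perf_counter() - t0, 3),
        }
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})

    volume = parcellation = tractogram = phantom_conn = None

    if stages.get("tensors"):
        t0 = time.perf_counter()
        tf = dict(config["tensor_field"])
        tf["bundles"] = _build_bundles(tf.get("bundles", []))
        spec = TensorFieldSpec(
            grid_dims=tuple(tf["grid_dims"]),
            voxel_size=tuple(tf.get("voxel_size", (1.0, 1.0, 1.0))),
            bundles=tf["bundles"],
            background_fa=tf.get("background_fa", 0.05),
            noise_sd=tf.get("noise_sd", 0.0),
            crossing_policy=tf.get("crossing_policy"),
            seed=derive_seed(master, "tensors"),
        )
        volume = make_tensor_field(spec)
        parcellation = make_parcellation(
            config["parcellation"]["n_per_hemisphere"],
            tuple(tf["grid_dims"]),
            tuple(tf.get("voxel_size", (1.0, 1.0, 1.0))),
        )
        (out / "tensors").mkdir(parents=True, exist_ok=True)
        tpath = out / "tensors" / "tensors.nii.gz"
        ppath = out / "tensors" / "parcellation.nii.gz"
        sio.save_tensor_nifti(volume, tpath)
        sio.save_parcellation_nifti(parcellation, ppath)
        record("tensors", t0, tensors=tpath, parcellation=ppath)

    if stages.get("tracking"):
        t0 = time.perf_counter()
        if volume is None:
            raise RuntimeError("tracking stage needs the tensors stage "
                               "(or a tensor NIfTI input): no tensor volume available")
        tcfg = TrackingConfig(**config["tracking"])
        tractogram = track(volume, tcfg)
        (out / "tracts").mkdir(parents=True, exist_ok=True)
        tckpath = out / "tracts" / "tracts.tck"
        sio.save_tck(tractogram, tckpath)
        record("tracking", t0, tracts=tckpath)

    if stages.get("connectome"):
        t0 = time.perf_counter()
        if tractogram is None or parcellation is None:
            raise RuntimeError("connectome stage needs tracking outputs: "
                               "no tractogram/parcellation available")
        phantom_conn = build_connectome(
            tractogram, parcellation, EdgeWeightConfig(**config["edge_weight"])
        )
        (out / "connectomes").mkdir(parents=True, exist_ok=True)
        cpath = out / "connectomes" / "phantom.tsv"
        sio.save_connectome_tsv(phantom_conn, cpath)
        record("connectome", t0, phantom_connectome=cpath)

    connectomes = table = None
    if stages.get("cohort"):
        t0 = time.perf_counter()
        ccfg = dict(config["cohort"])
        ccfg.pop("seed", None)  # stage seeds always derive from the master seed
        ccfg["apathy_edge_set"] = tuple(
            tuple(e) for e in ccfg.get("apathy_edge_set", ())
        )
        spec = CohortSpec(seed=derive_seed(master, "cohort"), **ccfg)
        connectomes, table = simulate_cohort(spec)
        (out / "connectomes").mkdir(parents=True, exist_ok=True)
        for i, conn in enumerate(connectomes):
            sio.save_connectome_tsv(conn, out / "connectomes" / f"sub-{i + 1:04d}.tsv")
        (out / "stats").mkdir(parents=True, exist_ok=True)
        cohort_path = out / "stats" / "cohort.csv"
        sio.save_cohort_csv(table, cohort_path)
        record("cohort", t0, cohort=cohort_path,
               connectome_dir=out / "connectomes")

    if stages.get("metrics"):
        t0 = time.perf_counter()
        if connectomes is None:
            raise RuntimeError("metrics stage needs the cohort stage: "
                               "no connectomes available")
        (out / "metrics").mkdir(parents=True, exist_ok=True)
        rows = []
        for i, conn in enumerate(connectomes):
            m = compute_metrics(conn)
            rows.append({"participant": i + 1, "density": m.density,
                         "global_efficiency": m.global_efficiency,
                         "local_efficiency": m.local_efficiency})
        mpath = out / "metrics" / "metrics.csv"
        pd.DataFrame(rows).to_csv(mpath, index=False)
        record("metrics", t0, metrics=mpath)

    if stages.get("nbs"):
        t0 = time.perf_counter()
        if connectomes is None or table is None:
            raise RuntimeError("nbs stage needs the cohort stage: "
                               "no connectomes/cohort table available")
        ncfg = config["nbs"]
        cols = {"intercept": np.ones(len(table)),
                ncfg["predictor"]: table[ncfg["predictor"]].to_numpy(float)}
        for cov in ncfg.get("covariates", []):
            cols[cov] = table[cov].to_numpy(float)
        design = DesignMatrix(pd.DataFrame(cols))
        cvec = np.zeros(len(cols))
        cvec[1] = 1.0
        contrast = Contrast(cvec, direction=ncfg.get("direction", "negative"))
        result = nbs_test(
            connectomes, design, contrast,
            t_threshold=ncfg["t_threshold"],
            n_permutations=ncfg["n_permutations"],
            alpha=ncfg["alpha"],
            seed=derive_seed(master, "nbs"),
        )
        (out / "nbs").mkdir(parents=True, exist_ok=True)
        comp_rows = []
        names = connectomes[0].node_names
        for ci, comp in enumerate(result.components):
            for i, j in comp:
                comp_rows.append({"component": ci + 1, "node_i": names[i],
                                  "node_j": names[j],
                                  "t": result.edge_t[i, j]})
        pd.DataFrame(comp_rows).to_csv(out / "nbs" / "components.tsv",
                                       sep="\t", index=False)
        pd.DataFrame({
            "component": np.arange(1, len(result.component_sizes) + 1),
            "size": result.component_sizes,
            "corrected_p": result.corrected_p,
            "significant": result.significant,
        }).to_csv(out / "nbs" / "corrected_p.csv", index=False)
        pd.DataFrame({"max_component_size": result.null_max_sizes}).to_csv(
            out / "nbs" / "null_distribution.csv", index=False)
        record("nbs", t0, nbs_dir=out / "nbs")

    if stages.get("stats"):
        t0 = time.perf_counter()
        if table is None:
            raise RuntimeError("stats stage needs the cohort stage: "
                               "no cohort table available")
        scfg = config["stats"]
        (out / "stats").mkdir(parents=True, exist_ok=True)
        t = table.copy()
        t["logWMH"] = log_transform(t["WMH"], "wmh")
        t["logLI"] = log_transform(t["LI"], "li")
        corr_cols = ["CESD", "age", "education", "MMSE", "logWMH", "logLI",
                     "density", "global_efficiency", "local_efficiency"]
        correlate(t, "AES", corr_cols).to_csv(
            out / "stats" / "correlations.csv", index=False)

        med_rows = []
        for name, x in [("WMH", t["logWMH"]), ("LI", t["logLI"])]:
            r = mediation_path(x, t["global_efficiency"], t["AES"])
            med_rows.append({"model": f"{name} -> efficiency -> AES",
                             "beta_total": r.beta_total, "p_total": r.p_total,
                             "beta_direct": r.beta_direct, "p_direct": r.p_direct,
                             "indirect": r.indirect})
        r = mediation_path(t["global_efficiency"], [t["logWMH"], t["logLI"]],
                           t["AES"])
        med_rows.append({"model": "efficiency -> AES | WMH + LI",
                         "beta_total": r.beta_total, "p_total": r.p_total,
                         "beta_direct": r.beta_direct, "p_direct": r.p_direct,
                         "indirect": r.indirect})
        pd.DataFrame(med_rows).to_csv(out / "stats" / "mediation.csv", index=False)

        preds = {"CESD": t["CESD"], "MMSE": t["MMSE"], "education": t["education"],
                 "age": t["age"], "logWMH": t["logWMH"], "logLI": t["logLI"],
                 "global_efficiency": t["global_efficiency"]}
        multiple_regression_standardized(t["AES"], preds).to_csv(
            out / "stats" / "multiple_regression.csv", index=False)

        covs = {c: t[c].to_numpy(float) for c in scfg.get("covariates", [])}
        anova_rows, tukey_rows = [], []
        if t["group"].nunique() >= 2:
            for outcome in ["density", "global_efficiency", "local_efficiency"]:
                tab = ancova_type2(t[outcome], t["group"], covs)
                tab.insert(0, "outcome", outcome)
                anova_rows.append(tab)
                tk = posthoc_tukey(t[outcome], t["group"], covs)
                tk.insert(0, "outcome", outcome)
                tukey_rows.append(tk)
            pd.concat(anova_rows).to_csv(out / "stats" / "ancova.csv", index=False)
            pd.concat(tukey_rows).to_csv(out / "stats" / "posthoc.csv", index=False)

        counts = pd.crosstab(t["group"], t["antidepressant"])
        if counts.shape == (counts.shape[0], 2) and counts.shape[0] >= 2 and \
                (counts.to_numpy() > 0).all():
            pairs = [(g, "control") for g in counts.index if g != "control"
                     and "control" in counts.index]
            cres = group_contingency(counts, pairs)
            with open(out / "stats" / "contingency.json", "w") as fh:
                json.dump({"chi2": cres.chi2, "p": cres.p, "dof": cres.dof,
                           "odds_ratios": cres.odds_ratios.to_dict("records")},
                          fh, indent=2)
        record("stats", t0, stats_dir=out / "stats")

    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
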