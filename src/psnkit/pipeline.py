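"""End-to-end orchestration: synthetic generation or PDB input, then
superposition, mobility/PCA, correlations, force constants, RSA, network
construction, centrality, communities/persistence, paths and reporting.

Every stage simply calls the corresponding library operation, so pipeline
outputs equal what the stage functions return when called directly; all
randomness flows from the single config seed.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
import yaml

from . import dynamics, network, stability, synthetic
from .structure import Ensemble, StructureModel, parse_pdb, select_atoms, \
    write_multimodel_pdb

log = logging.getLogger("psnkit")

STAGES = ("simulate", "mobility", "stability", "network", "communities",
          "paths", "report")


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@dataclass
class SyntheticSpec:
    """Study-condition defaults for the planted two-module system.

    The rigid core spans domain A and the inter-domain clamp (a spine-like
    stretch crossing the interface); the far-domain bulk is flexible.  The
    bridge residue is planted with genuine correlation to both domains, as
    befits the communication mediator.
    """
    n_residues: int = 50
    geometry: str = "two_domain"
    n_frames: int = 5000
    rigid_scale: float = 0.05       # A^2 per coordinate, rigid core
    flexible_scale: float = 0.5     # A^2 per coordinate, flexible bulk
    rho: float = 0.8                # intra-module displacement correlation
    bridge_correlation: float = 0.6
    background_correlation: float = 0.0
    flicker_fraction: float = 0.0   # fraction of frame blocks with module
    flicker_module: str = "A"       # contacts of this module broken


@dataclass
class PipelineConfig:
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    input_pdb: str | None = None
    selection: str = "backbone_heavy"
    temperature: float = 300.0          # K
    exclude_neighbors: int = 1
    i_min: float = network.DEFAULT_I_MIN                 # %
    contact_cutoff: float = 4.5                          # A
    atom_scope: str = "sidechain_heavy"
    hub_min_degree: int = network.DEFAULT_HUB_MIN_DEGREE
    k_clique: int = network.DEFAULT_K_CLIQUE
    persistence_min: float = network.DEFAULT_PERSISTENCE_MIN
    match_jaccard: float = network.DEFAULT_MATCH_JACCARD
    corr_min: float = network.DEFAULT_CORR_BOUNDS[0]
    corr_max: float = network.DEFAULT_CORR_BOUNDS[1]
    rsa_buried: float = stability.RSA_BURIED_MAX         # %
    rsa_exposed: float = stability.RSA_EXPOSED_MIN       # %
    n_blocks: int = 10
    n_modes: int = 3
    superpose: str = "auto"     # "auto" skips the fit for ensembles whose
                                # frames are already reference-aligned
    centrality_mode: str = "block_mean"   # or "consensus"
    run_paths: bool = True
    path_source: str | None = None
    path_target: str | None = None
    path_tolerance: float = 1.0
    seed: int = 0
    output_dir: str = "results/pipeline"

    def validate(self) -> None:
        checks = [
            (0.0 <= self.i_min <= 100.0, "i_min must be in [0, 100] %"),
            (self.contact_cutoff > 0, "contact_cutoff must be positive"),
            (self.temperature > 0, "temperature must be positive"),
            (self.hub_min_degree >= 1, "hub_min_degree must be >= 1"),
            (self.k_clique >= 3, "k_clique must be >= 3"),
            (0.0 <= self.persistence_min <= 1.0,
             "persistence_min must be in [0, 1]"),
            (0.0 < self.match_jaccard <= 1.0,
             "match_jaccard must be in (0, 1]"),
            (0.0 <= self.corr_min <= self.corr_max <= 1.0,
             "correlation filter bounds must satisfy 0 <= min <= max <= 1"),
            (0.0 <= self.rsa_buried < self.rsa_exposed <= 100.0,
             "RSA thresholds must satisfy 0 <= buried < exposed <= 100"),
            (self.n_blocks >= 2, "n_blocks must be >= 2"),
            (self.n_modes >= 1, "n_modes must be >= 1"),
            (self.centrality_mode in ("block_mean", "consensus"),
             "centrality_mode must be block_mean or consensus"),
            (self.superpose in ("auto", "always"),
             "superpose must be auto or always"),
            (self.selection in ("backbone_heavy", "calpha", "heavy"),
             "selection must be a named backbone selection"),
            (self.synthetic is not None or self.input_pdb is not None,
             "either synthetic spec or input_pdb is required"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if syn is not None:
            d["synthetic"] = SyntheticSpec(**syn)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class AnalysisReport:
    residue_table: pd.DataFrame
    communities: list
    persistent_communities: list
    edge_persistence: dict
    paths: list
    scatter_stats: dict
    pca_summary: dict
    consensus_graph: "network.PSNGraph"
    manifest: dict
    model: StructureModel
    ensemble: Ensemble


# ----------------------------------------------------------------------

def build_synthetic_system(spec: SyntheticSpec, seed: int):
    """Toy model + planted covariance + sampled ensemble for the study
    conditions; returns (model, ensemble, layout)."""
    toy = synthetic.ToyStructureSpec(n_residues=spec.n_residues,
                                     geometry=spec.geometry, seed=seed)
    model = synthetic.build_toy_structure(toy)
    cross = ()
    if spec.geometry == "two_domain":
        mod_a, bridge, mod_b = synthetic.two_domain_layout(spec.n_residues)
        # rigid core = domain A plus the inter-domain clamp
        rigid = set(mod_a) | set(range(bridge - 4, bridge + 5))
        cross = (synthetic.CrossCorrelation(
            bridge, mod_a + mod_b, spec.bridge_correlation),)
    else:
        half = spec.n_residues // 2
        mod_a = tuple(range(half))
        bridge = None
        mod_b = tuple(range(half, spec.n_residues))
        rigid = set(mod_a)
    scale = np.full(spec.n_residues, spec.flexible_scale)
    scale[sorted(rigid)] = spec.rigid_scale
    cov_spec = synthetic.PlantedCovarianceSpec(
        per_residue_scale=scale,
        modules=(synthetic.CorrelationModule(mod_a, spec.rho),
                 synthetic.CorrelationModule(mod_b, spec.rho)),
        background_correlation=spec.background_correlation,
        cross_links=cross)
    cov = synthetic.make_planted_covariance(cov_spec, model)
    flicker = None
    if spec.flicker_fraction > 0:
        module = mod_a if spec.flicker_module == "A" else mod_b
        flicker = synthetic.FlickerSpec(module=module,
                                        fraction=spec.flicker_fraction)
    ensemble = synthetic.sample_ensemble(model, cov, spec.n_frames,
                                         seed=seed, flicker=flicker)
    layout = {"module_a": mod_a, "bridge": bridge, "module_b": mod_b,
              "rigid_core": tuple(sorted(rigid)),
              "covariance_spec": cov_spec}
    return model, ensemble, layout


def run_pipeline(config: PipelineConfig,
                 upto: str = "report") -> AnalysisReport:
    """Execute the pipeline stages in order up to ``upto``.

    Raises ConfigError before any computation for an invalid config; stage
    failures propagate with the stage name prefixed.
    """
    config.validate()
    if upto not in STAGES:
        raise ConfigError(f"unknown stage {upto!r}; valid: {STAGES}")
    last = STAGES.index(upto)
    timings = {}
    state: dict = {}

    def stage(name, fn):
        if STAGES.index(name) > last:
            return False
        t0 = time.perf_counter()
        try:
            fn()
        except ConfigError:
            raise
        except Exception as exc:
            raise PipelineStageError(f"[stage {name}] {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s finished in %.2f s", name, timings[name])
        return True

    # -- simulate / load ------------------------------------------------
    def _simulate():
        if config.synthetic is not None:
            model, ensemble, layout = build_synthetic_system(
                config.synthetic, config.seed)
        else:
            text = FsPath(config.input_pdb).read_text()
            model, ensemble = parse_pdb(text)
            if ensemble is None:
                raise ConfigError(
                    "input PDB must contain multiple MODEL frames")
            layout = {}
        state.update(model=model, ensemble=ensemble, layout=layout)
    stage("simulate", _simulate)

    # -- mobility / PCA / correlations ----------------------------------
    def _mobility():
        model, ensemble = state["model"], state["ensemble"]
        mask = select_atoms(model, config.selection)
        if config.superpose == "auto" and ensemble.meta.get("aligned"):
            fitted = ensemble
        else:
            fitted = dynamics.superpose(ensemble, mask=mask)
        mobility = dynamics.rmsf_bfactors(fitted, mask)
        pca = dynamics.pca_modes(fitted, mask)
        n_modes = min(config.n_modes, pca.n_modes)
        mode_msd, mode_b = dynamics.mode_mobility(pca, n_modes)
        corr = dynamics.cross_correlation(fitted)
        state.update(mask=mask, fitted=fitted, mobility=mobility, pca=pca,
                     mode_msd=mode_msd, mode_b=mode_b, corr=corr)
    stage("mobility", _mobility)

    # -- stability profiles ---------------------------------------------
    def _stability():
        model = state["model"]
        fc = stability.force_constants(
            state["fitted"], temperature=config.temperature,
            exclude_neighbors=config.exclude_neighbors)
        rsa = stability.sasa_rsa(model, buried_max=config.rsa_buried,
                                 exposed_min=config.rsa_exposed)
        centers = stability.stabilization_centers(
            model, contact_cutoff=config.contact_cutoff)
        state.update(fc=fc, rsa=rsa, centers=centers)
    stage("stability", _stability)

    # -- network construction and centrality ----------------------------
    def _network():
        model, ensemble = state["model"], state["ensemble"]
        i_mat, keys = network.interaction_strength_matrix(
            model, ensemble, contact_cutoff=config.contact_cutoff,
            atom_scope=config.atom_scope)
        consensus = network.build_psn(i_mat, state["corr"], keys,
                                      i_min=config.i_min)
        blocks = network.ensemble_block_graphs(
            model, ensemble, state["corr"], n_blocks=config.n_blocks,
            i_min=config.i_min, contact_cutoff=config.contact_cutoff,
            atom_scope=config.atom_scope)
        deg = network.degree_and_hubs(consensus, config.hub_min_degree)
        if config.centrality_mode == "consensus":
            closeness, isolated = network.closeness_profile(consensus)
            betweenness = network.betweenness_profile(consensus)
        else:
            clo_blocks, bet_blocks = [], []
            for g in blocks:
                c, _ = network.closeness_profile(g)
                clo_blocks.append(c)
                bet_blocks.append(network.betweenness_profile(g))
            closeness = np.mean(clo_blocks, axis=0)
            betweenness = np.mean(bet_blocks, axis=0)
            _, isolated = network.closeness_profile(consensus)
        state.update(i_mat=i_mat, node_keys=keys, consensus=consensus,
                     blocks=blocks, degree=deg, closeness=closeness,
                     betweenness=betweenness, isolated=isolated)
    stage("network", _network)

    # -- communities and persistence ------------------------------------
    def _communities():
        consensus, blocks = state["consensus"], state["blocks"]
        comms = network.cpm_communities(consensus, k=config.k_clique)
        persistent = network.community_persistence(
            blocks, k=config.k_clique,
            persistence_min=config.persistence_min,
            match_jaccard=config.match_jaccard)
        edges = network.edge_persistence(blocks, config.persistence_min)
        state.update(communities=comms, persistent=persistent,
                     edge_persist=edges)
    stage("communities", _communities)

    # -- allosteric paths ------------------------------------------------
    def _paths():
        if not config.run_paths:
            state["paths"] = []
            return
        keys = state["model"].residue_keys()
        source = config.path_source or keys[0]
        target = config.path_target or keys[-1]
        best = network.shortest_allosteric_path(
            state["consensus"], source, target,
            corr_min=config.corr_min, corr_max=config.corr_max)
        ensemble_paths = [best]
        if best.connected and config.path_tolerance > 0:
            ensemble_paths = network.suboptimal_paths(
                state["consensus"], source, target, config.path_tolerance,
                corr_min=config.corr_min, corr_max=config.corr_max,
                max_paths=50)
        state["paths"] = ensemble_paths
    stage("paths", _paths)

    # -- report -----------------------------------------------------------
    def _report():
        state["report_df"] = _residue_table(config, state)
        fc_k = state["fc"].k
        scatter = {}
        for name, other in (
                ("force_constant_vs_closeness",
                 state["closeness"][:len(fc_k)]),
                ("force_constant_vs_rsa", state["rsa"].rsa)):
            try:
                scatter[name] = asdict(
                    stability.profile_correlation(fc_k, other))
            except stability.StabilityError as exc:
                scatter[name] = {"error": str(exc)}
        state["scatter"] = scatter
    stage("report", _report)

    pca = state.get("pca")
    pca_summary = {}
    if pca is not None:
        pca_summary = {
            "top3_variance_fraction": float(
                pca.variance_fractions[:3].sum()),
            "top10_variance_fraction": float(
                pca.variance_fractions[:10].sum()),
            "n_modes": int(pca.n_modes),
        }
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "stages_run": [s for s in timings],
                "package": "psnkit 0.1.0"}
    return AnalysisReport(
        residue_table=state.get("report_df", pd.DataFrame()),
        communities=state.get("communities", []),
        persistent_communities=state.get("persistent", []),
        edge_persistence=state.get("edge_persist", {}),
        paths=state.get("paths", []),
        scatter_stats=state.get("scatter", {}),
        pca_summary=pca_summary,
        consensus_graph=state.get("consensus"),
        manifest=manifest,
        model=state.get("model"),
        ensemble=state.get("ensemble"))


def _residue_table(config: PipelineConfig, state: dict) -> pd.DataFrame:
    model = state["model"]
    keys = model.residue_keys()
    n = len(keys)
    chains = [model.groups[g]["chain_id"] for g in model.residue_groups]
    resids = [model.groups[g]["author_resid"] for g in model.residue_groups]
    names = [model.groups[g]["res_name"] for g in model.residue_groups]
    deg = state["degree"]
    df = pd.DataFrame({
        "key": keys, "chain": chains, "author_resid": resids,
        "res_name": names,
        "rmsf": state["mobility"].rmsf,
        "bfactor": state["mobility"].bfactor,
        "mode_mobility": state["mode_msd"],
        "force_constant": state["fc"].k,
        "force_constant_capped": state["fc"].capped,
        "sasa": state["rsa"].sasa,
        "rsa": state["rsa"].rsa,
        "rsa_class": state["rsa"].rsa_class,
        "stabilization_center": state["centers"].flagged,
        "degree": deg.degree[:n],
        "hub": deg.hub[:n],
        "closeness": state["closeness"][:n],
        "betweenness": state["betweenness"][:n],
        "isolated": state["isolated"][:n],
    })
    return df


def generate_report(report: AnalysisReport, output_dir) -> dict:
    """Write residue profiles, community/path JSON, graph files and the
    run manifest; returns the mapping of artifact names to paths."""
    out = FsPath(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def _write_json(name, obj):
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        artifacts[name] = str(path)

    if len(report.residue_table):
        path = out / "residue_profiles.csv"
        report.residue_table.to_csv(path, index=False, float_format="%.8g")
        artifacts["residue_profiles.csv"] = str(path)
    _write_json("communities.json", {
        "consensus": network.communities_to_json(report.communities),
        "persistent": network.communities_to_json(
            report.persistent_communities),
        "edge_persistence": {" | ".join(k): v for k, v in
                             report.edge_persistence.items()},
    })
    _write_json("paths.json", network.paths_to_json(report.paths))
    _write_json("scatter_stats.json", report.scatter_stats)
    _write_json("pca_summary.json", report.pca_summary)
    _write_json("manifest.json", report.manifest)
    if report.consensus_graph is not None:
        network.write_edge_tsv(report.consensus_graph, out / "edges.tsv")
        network.write_graphml(report.consensus_graph, out / "graph.graphml")
        artifacts["edges.tsv"] = str(out / "edges.tsv")
        artifacts["graph.graphml"] = str(out / "graph.graphml")
    return artifacts


def write_ensemble_pdb(report: AnalysisReport, output_dir,
                       max_frames: int = 25) -> str:
    """Down-sampled multi-model PDB of the analyzed ensemble."""
    out = FsPath(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ens = report.ensemble
    step = max(1, ens.n_frames // max_frames)
    sub = Ensemble(frames=ens.frames[::step][:max_frames],
                   model=report.model)
    path = out / "ensemble_sample.pdb"
    path.write_text(write_multimodel_pdb(report.model, sub))
    return str(path)
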