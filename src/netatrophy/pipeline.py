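"""End-to-end orchestration: load inputs, run every stage, write tidy outputs.

Each stage is a pure function of (inputs, config, seeds) and writes its own
TSV/JSON artifacts, so reruns with the same configuration are byte
identical. A manifest records the configuration, seeds and package version.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biotype import cluster_biotypes, compare_subgroups, similarity_matrix
from .datatypes import CohortData, ConnectomeSet
from .enrichment import system_permutation_test
from .epicenter import epicenter_significance
from .io import (
    read_cohort,
    read_parcellation,
    read_square_matrix,
    read_system_assignment,
    write_regional_table,
    write_square_matrix,
)
from .morphometry import fit_wscores, group_difference
from .networks import (
    build_morphological_network,
    network_weighted_wscores,
    neighbor_atrophy,
    weighted_degree,
)
from .pls import behavior_loadings, fit_pls, pls_permutation
from .spin import generate_spins, spin_correlation_test

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("netatrophy")

STAGES = ("group_diff", "networks", "models", "epicenter", "enrichment",
          "wscores", "pls", "cluster")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Paths and knobs for a full pipeline run (YAML-compatible flat keys)."""

    parcellation: str
    sc: str
    fc: str
    thickness: str
    subjects: str
    output_dir: str
    systems: str | None = None
    n_spins: int = 5000
    n_perm_pls: int = 5000
    kmeans_restarts: int = 100
    k_min: int = 2
    k_max: int = 10
    seed: int = 0
    normalization: str = "weight_sum"
    negative_weights: str = "clamp"
    tail: str = "two"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_inputs(config: RunConfig):
    try:
        scheme = read_parcellation(config.parcellation)
    except OSError as err:
        raise PipelineError("load", "missing_parcellation", str(err)) from err
    try:
        sc = read_square_matrix(config.sc, scheme)
        fc = read_square_matrix(config.fc, scheme)
    except OSError as err:
        raise PipelineError("networks", "missing_connectome", str(err)) from err
    connectomes = ConnectomeSet(frame=scheme, sc=sc, fc=fc)
    try:
        cohort = read_cohort(config.thickness, config.subjects, scheme)
    except OSError as err:
        raise PipelineError("load", "missing_cohort", str(err)) from err
    assignments = []
    if config.systems:
        for atlas in ("yeo7", "von_economo"):
            try:
                assignments.append(read_system_assignment(config.systems, scheme, atlas))
            except (OSError, ValueError):
                continue
    return scheme, connectomes, cohort, assignments


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns a results dictionary.

    Stage order: group GLM -> SMN from controls -> centrality + neighbor
    models with spin tests -> epicenter ranking -> system enrichment ->
    W-scores and network-weighted W -> behavioral PLS -> biotype clustering.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme, connectomes, cohort, assignments = _load_inputs(config)
    results: dict = {}
    t0 = time.time()

    spins = generate_spins(scheme, config.n_spins, seed=config.seed)
    controls, _ = cohort.split()

    def stage_on(name):
        return name in stages

    gdm = None
    if stage_on("group_diff") or stage_on("models") or stage_on("epicenter") \
            or stage_on("enrichment"):
        try:
            gdm = group_difference(cohort)
        except ValueError as err:
            raise PipelineError("group_diff", "glm_failure", str(err)) from err
        if stage_on("group_diff"):
            df = gdm.to_frame().reset_index(names="name")
            df.to_csv(out / "group_difference.tsv", sep="\t", index=False)
            results["group_diff"] = gdm
            log.info("group_diff done (%d significant) [%.1fs]",
                     int(gdm.significant.sum()), time.time() - t0)

    smn = build_morphological_network(controls)
    connectomes.smn = smn
    if stage_on("networks"):
        write_square_matrix(smn, scheme, out / "smn.tsv")
        deg = pd.DataFrame({
            "degree_sc": weighted_degree(connectomes.sc, "sc"),
            "degree_smn": weighted_degree(smn, "smn"),
            "degree_fc": weighted_degree(connectomes.fc, "fc"),
        })
        write_regional_table(deg, scheme, out / "degree_centrality.tsv")
        results["networks"] = deg
        log.info("networks done [%.1fs]", time.time() - t0)

    if stage_on("models"):
        z = gdm.z
        rows = []
        neighbor_maps = {
            "sc_unweighted": neighbor_atrophy(z, connectomes.sc, None,
                                              config.normalization,
                                              config.negative_weights),
            "smn_weighted": neighbor_atrophy(z, connectomes.sc, smn,
                                             config.normalization,
                                             config.negative_weights),
            "fc_weighted": neighbor_atrophy(z, connectomes.sc, connectomes.fc,
                                            config.normalization,
                                            config.negative_weights),
        }
        for modality, matrix in (("sc", connectomes.sc), ("smn", smn),
                                 ("fc", connectomes.fc)):
            r, p = spin_correlation_test(z, weighted_degree(matrix, modality),
                                         spins, tail=config.tail)
            rows.append({"model": "nodal_stress", "modality": modality,
                         "r": r, "p_spin": p})
        for name, nb_map in neighbor_maps.items():
            r, p = spin_correlation_test(z, nb_map, spins, tail=config.tail)
            rows.append({"model": "neighbor", "modality": name, "r": r, "p_spin": p})
        model_table = pd.DataFrame(rows)
        model_table.to_csv(out / "network_models.tsv", sep="\t", index=False)
        nb_df = pd.DataFrame(neighbor_maps)
        write_regional_table(nb_df, scheme, out / "neighbor_atrophy.tsv")
        results["models"] = model_table
        log.info("models done [%.1fs]", time.time() - t0)

    if stage_on("epicenter"):
        epi = epicenter_significance(gdm.z, connectomes.sc, smn, spins,
                                     config.normalization, config.negative_weights)
        epi.to_frame().reset_index(names="name").to_csv(
            out / "epicenter.tsv", sep="\t", index=False)
        results["epicenter"] = epi
        log.info("epicenter done [%.1fs]", time.time() - t0)

    if stage_on("enrichment") and assignments:
        tables = []
        for assignment in assignments:
            table = system_permutation_test(gdm.z, assignment, spins=spins)
            table.insert(0, "atlas", assignment.atlas_name)
            tables.append(table)
        enrich = pd.concat(tables, ignore_index=True)
        enrich.to_csv(out / "system_enrichment.tsv", sep="\t", index=False)
        results["enrichment"] = enrich
        log.info("enrichment done [%.1fs]", time.time() - t0)

    wsm = fit_wscores(cohort)
    smn_w = network_weighted_wscores(wsm.w, connectomes.sc, smn,
                                     config.normalization, config.negative_weights)
    patient_ids = cohort.subjects.loc[cohort.is_patient, "subject"].to_numpy()
    if stage_on("wscores"):
        wdf = pd.DataFrame(wsm.w, columns=scheme.names)
        wdf.insert(0, "subject", patient_ids)
        wdf.to_csv(out / "wscores.tsv", sep="\t", index=False)
        sdf = pd.DataFrame(smn_w, columns=scheme.names)
        sdf.insert(0, "subject", patient_ids)
        sdf.to_csv(out / "network_weighted_wscores.tsv", sep="\t", index=False)
        results["wscores"] = wsm
        results["smn_w"] = smn_w
        log.info("wscores done [%.1fs]", time.time() - t0)

    # regions without usable neighborhoods yield all-NaN SMN-W columns and
    # are excluded from the patient-level multivariate stages
    usable = np.isfinite(smn_w).all(axis=0)
    smn_w_used = smn_w[:, usable]

    if stage_on("pls"):
        clinical = cohort.subjects.loc[
            cohort.is_patient, list(CohortData.CLINICAL)].to_numpy(dtype=float)
        try:
            res = fit_pls(smn_w_used, clinical)
            res.perm_p = pls_permutation(smn_w_used, clinical,
                                         n_perm=config.n_perm_pls, seed=config.seed)
            ok = np.isfinite(clinical).all(axis=1)
            res.behavior_loadings = behavior_loadings(clinical[ok], res.brain_scores)
        except ValueError as err:
            raise PipelineError("pls", "pls_failure", str(err)) from err
        saliences = np.full((scheme.n_regions, res.brain_saliences.shape[1]), np.nan)
        saliences[usable] = res.brain_saliences
        write_regional_table(
            pd.DataFrame(saliences,
                         columns=[f"lv{i+1}" for i in range(saliences.shape[1])]),
            scheme, out / "pls_brain_saliences.tsv")
        pd.DataFrame(
            res.behavior_saliences, index=list(CohortData.CLINICAL),
            columns=[f"lv{i+1}" for i in range(res.behavior_saliences.shape[1])],
        ).rename_axis("measure").reset_index().to_csv(
            out / "pls_behavior_saliences.tsv", sep="\t", index=False)
        summary = {
            "singular_values": res.singular_values.tolist(),
            "covariance_explained": res.covariance_explained.tolist(),
            "perm_p": res.perm_p.tolist(),
            "n_used": res.n_used,
        }
        (out / "pls_summary.json").write_text(json.dumps(summary, indent=2))
        results["pls"] = res
        log.info("pls done (LV1 %.1f%%, p=%.4f) [%.1fs]",
                 100 * res.covariance_explained[0], res.perm_p[0], time.time() - t0)

    if stage_on("cluster"):
        try:
            sim = similarity_matrix(smn_w_used)
            k_max = min(config.k_max, sim.shape[0] - 1)
            clus = cluster_biotypes(sim, range(config.k_min, k_max + 1),
                                    restarts=config.kmeans_restarts, seed=config.seed)
            contrasts = compare_subgroups(clus.labels, cohort) \
                if clus.chosen_k == 2 else None
        except ValueError as err:
            raise PipelineError("cluster", "cluster_failure", str(err)) from err
        pd.DataFrame({"subject": patient_ids, "biotype": clus.labels}).to_csv(
            out / "biotypes.tsv", sep="\t", index=False)
        clus.silhouette.rename_axis("k").reset_index().to_csv(
            out / "silhouette.tsv", sep="\t", index=False)
        if contrasts is not None:
            contrasts.to_csv(out / "subgroup_contrasts.tsv", sep="\t", index=False)
        results["cluster"] = clus
        results["contrasts"] = contrasts
        log.info("cluster done (k=%d) [%.1fs]", clus.chosen_k, time.time() - t0)

    manifest = {
        "package": "netatrophy",
        "version": __version__,
        "config": asdict(config),
        "stages": list(stages),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
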