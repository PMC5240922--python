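"""Stage runners: coevolution → dynamics → network → pathways.

Each stage writes plain TSV/JSON artifacts with provenance headers into
``config.outdir`` and returns its in-memory results; downstream stages
accept those results directly (``run_all``) or reload what they need
from the artifacts of an earlier command.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    cluster_weights,
    filter_columns,
    map_alignment_to_structure,
    read_alignment,
)
from .coevolution import cmi_profile, kl_conservation, zscore_mi
from .config import RunConfig
from .coupling import coupling_matrix, pmi_profile
from .ensemble import read_ensemble, rmsf
from .errors import InputError
from .gnm import build_gnm, slow_mode_fluctuations
from .io import provenance_lines, read_json, read_tsv, write_json, write_tsv
from .network import (
    betweenness,
    build_contact_graph,
    girvan_newman,
    persistent_communities,
    ResidueGraph,
    CommunityPartition,
)
from .pathways import annotate_hops, communication_propensity, path_ensemble

log = logging.getLogger("allonet")


def _header(config: RunConfig) -> list[str]:
    return provenance_lines(config.items(), config.hash(), __version__)


def _require(path: Path, prior_command: str) -> Path:
    if not path.exists():
        raise InputError(
            f"required artifact {path} not found; run `allonet {prior_command}` first"
        )
    return path


def run_coevo(config: RunConfig):
    """Alignment → weights → Z-scored MI, KL conservation, cMI profile."""
    config.validate()
    if config.msa is None:
        raise InputError("config.msa (alignment path) is required")
    out = Path(config.outdir)
    aln = read_alignment(config.msa, reference_id=None)
    # reference: a row literally named 'reference' if present, else the first
    ref_id = "reference" if "reference" in aln.sequence_ids else aln.sequence_ids[0]
    aln.reference_id = ref_id
    aln = filter_columns(aln, config.min_coverage)
    weights = cluster_weights(aln, config.identity_threshold)
    log.info("coevo: %d sequences, %d columns, %d clusters",
             aln.n_sequences, aln.n_columns, weights.cluster_count)
    coevo = zscore_mi(
        aln, weights,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
        pseudocount=config.pseudocount,
    )
    cons = kl_conservation(aln, weights)
    cmi = cmi_profile(coevo, t=config.t_cmi, matrix=config.cmi_matrix)

    mapping = None
    ref_res = np.full(aln.n_columns, -1)
    if config.ensemble is not None:
        structure = read_ensemble(config.ensemble).structure
        mapping = map_alignment_to_structure(
            aln, structure.residue_numbers, structure.sequence
        )
        for k, col in enumerate(aln.column_index):
            ref_res[k] = mapping.column_to_residue.get(int(col), -1)
    header = _header(config)
    write_tsv(
        out / "columns.tsv",
        pd.DataFrame(
            {
                "column": aln.column_index,
                "reference_residue": ref_res,
                "kl": cons.scores,
                "cmi": cmi.cmi,
            }
        ),
        header,
    )
    iu = np.triu_indices(aln.n_columns, 1)
    write_tsv(
        out / "pairs.tsv",
        pd.DataFrame(
            {
                "i": aln.column_index[iu[0]],
                "j": aln.column_index[iu[1]],
                "raw_mi": coevo.raw_mi[iu],
                "apc_mi": coevo.apc_mi[iu],
                "z_mi": coevo.z_mi[iu],
            }
        ),
        header,
    )
    return {"alignment": aln, "weights": weights, "coevo": coevo,
            "conservation": cons, "cmi": cmi, "mapping": mapping}


def run_dynamics(config: RunConfig):
    """Ensemble → GNM slow-mode profile and Cα RMSF."""
    config.validate()
    if config.ensemble is None:
        raise InputError("config.ensemble (multi-model PDB path) is required")
    out = Path(config.outdir)
    ens = read_ensemble(config.ensemble)
    gnm = build_gnm(ens.structure, cutoff=config.gnm_cutoff)
    slow = slow_mode_fluctuations(gnm, n_modes=config.gnm_modes)
    header = _header(config)
    chains = [r.chain for r in ens.structure.residues]
    gnm_chains = [
        c for c, r in zip(chains, ens.structure.residues)
        if r.number in set(gnm.residue_numbers)
    ]
    write_tsv(
        out / "gnm_profile.tsv",
        pd.DataFrame(
            {
                "residue": slow.residue_numbers,
                "chain": gnm_chains,
                "value": slow.values,
                "hinge": slow.hinges.astype(int),
            }
        ),
        header,
    )
    result = {"ensemble": ens, "gnm": gnm, "slow_modes": slow}
    if ens.frame_count >= 2:
        prof = rmsf(ens)
        write_tsv(
            out / "rmsf.tsv",
            pd.DataFrame(
                {"residue": prof.residue_numbers, "chain": chains, "value": prof.values}
            ),
            header,
        )
        result["rmsf"] = prof
    log.info("dynamics: %d residues, %d frames", ens.structure.n_residues, ens.frame_count)
    return result


def _cmi_by_residue(ensemble, columns: pd.DataFrame) -> np.ndarray:
    """cMI mapped from alignment columns onto structure residues (0 where
    unmapped)."""
    cmi = np.zeros(ensemble.structure.n_residues)
    pos = {num: k for k, num in enumerate(ensemble.structure.residue_numbers)}
    mapped = columns[columns["reference_residue"] >= 0]
    for _, row in mapped.iterrows():
        k = pos.get(int(row["reference_residue"]))
        if k is not None:
            cmi[k] = row["cmi"]
    return cmi


def run_network(config: RunConfig, coevo_result=None, dynamics_result=None):
    """pMI, coupling matrix, mean-frame graph, centrality, communities."""
    config.validate()
    out = Path(config.outdir)
    if config.ensemble is None:
        raise InputError("config.ensemble (multi-model PDB path) is required")
    ens = (
        dynamics_result["ensemble"] if dynamics_result
        else read_ensemble(config.ensemble)
    )
    if coevo_result is not None:
        aln = coevo_result["alignment"]
        mapping = coevo_result["mapping"]
        if mapping is None:
            mapping = map_alignment_to_structure(
                aln, ens.structure.residue_numbers, ens.structure.sequence
            )
        cmi_res = np.zeros(ens.structure.n_residues)
        pos = {num: k for k, num in enumerate(ens.structure.residue_numbers)}
        for k, col in enumerate(aln.column_index):
            res = mapping.column_to_residue.get(int(col))
            if res is not None:
                cmi_res[pos[res]] = coevo_result["cmi"].cmi[k]
    else:
        columns = read_tsv(_require(out / "columns.tsv", "coevo"))
        if (columns["reference_residue"] < 0).all():
            raise InputError(
                "columns.tsv has no structure mapping; rerun `allonet coevo` "
                "with the ensemble path set"
            )
        cmi_res = _cmi_by_residue(ens, columns)

    pmi = pmi_profile(ens, cmi_res, threshold=config.t_pmi,
                      aggregate=config.pmi_aggregate)
    coup = coupling_matrix(ens, pmi, estimator=config.estimator)
    header = _header(config)
    numbers = ens.structure.residue_numbers
    write_tsv(
        out / "pmi.tsv",
        pd.DataFrame({"residue": numbers, "mean_pmi": pmi.mean}),
        header,
    )
    iu = np.triu_indices(coup.n_residues, 1)
    write_tsv(
        out / "coupling.tsv",
        pd.DataFrame(
            {
                "i": np.asarray(numbers)[iu[0]],
                "j": np.asarray(numbers)[iu[1]],
                "r_mi": coup.r_mi[iu],
                "w": coup.w[iu],
            }
        ),
        header,
    )
    mean_frame = ens.frames.mean(axis=0)
    graph = build_contact_graph(
        ens.structure, mean_frame, coup,
        I_min=config.I_min, contact_cutoff=config.contact_distance,
    )
    cent = betweenness(graph)
    write_tsv(
        out / "centrality.tsv",
        pd.DataFrame(
            {
                "residue": [numbers[i] for i in cent.nodes],
                "raw": cent.raw,
                "normalized": cent.normalized,
            }
        ),
        header,
    )
    edge_rows = [
        (numbers[u], numbers[v], d["strength"], d["length"])
        for u, v, d in graph.g.edges(data=True)
    ]
    write_tsv(
        out / "edges.tsv",
        pd.DataFrame(edge_rows, columns=["i", "j", "strength", "length"]),
        header,
    )
    partition = girvan_newman(graph)
    stride = max(ens.frame_count // config.community_frames, 1)
    frame_ids = list(range(0, ens.frame_count, stride))[: config.community_frames]
    frame_partitions = []
    for f in frame_ids:
        fg = build_contact_graph(
            ens.structure, ens.frames[f], coup,
            I_min=config.I_min, contact_cutoff=config.contact_distance, frame=f,
        )
        frame_partitions.append(girvan_newman(fg))
    persistent = persistent_communities(frame_partitions, persistence=config.persistence)
    log.info(
        "network: %d edges, %d communities (Q=%.3f), %d persistent",
        graph.g.number_of_edges(), len(partition.communities),
        partition.modularity, len(persistent),
    )
    write_json(
        out / "communities.json",
        {
            "modularity": partition.modularity,
            "communities": [sorted(c) for c in partition.communities],
            "persistent": [
                {"residues": sorted(p.communities[0]), "persistence": p.persistence}
                for p in persistent
            ],
            "frames_sampled": frame_ids,
        },
        header,
    )
    return {
        "ensemble": ens, "pmi": pmi, "coupling": coup, "graph": graph,
        "centrality": cent, "partition": partition, "persistent": persistent,
    }


def run_pathways(config: RunConfig, network_result=None):
    """CP profile and source→sink path ensemble with hop annotation."""
    config.validate()
    out = Path(config.outdir)
    if network_result is None:
        _require(out / "communities.json", "network")
        network_result = run_network(config)
    ens = network_result["ensemble"]
    pmi = network_result["pmi"]
    coup = network_result["coupling"]
    partition = network_result["partition"]
    cp = communication_propensity(
        ens, pmi, w1=config.w1, w2=config.w2, temperature=config.temperature
    )
    header = _header(config)
    write_tsv(
        out / "cp.tsv",
        pd.DataFrame({"residue": cp.residue_numbers, "cp_kbt": cp.cp}),
        header,
    )
    result = {"cp": cp, **network_result}
    if config.source is None or config.sink is None:
        log.info("pathways: no source/sink configured; CP profile only")
        return result
    ensemble_paths = path_ensemble(
        ens, coup, source=config.source, sink=config.sink,
        I_min=config.I_min, contact_cutoff=config.contact_distance,
        mode=config.path_mode,
    )
    for p in ensemble_paths.paths:
        annotate_hops(p, partition, cp)
    write_json(
        out / "paths.json",
        {
            "source": ensemble_paths.source,
            "sink": ensemble_paths.sink,
            "n_frames": ensemble_paths.n_frames,
            "n_connected_frames": ensemble_paths.n_connected_frames,
            "paths": [
                {
                    "residues": list(p.residues),
                    "occupancy": p.occupancy,
                    "length": p.length,
                    "hops": [
                        {
                            "from_residue": h.from_residue,
                            "to_residue": h.to_residue,
                            "from_community": h.from_community,
                            "to_community": h.to_community,
                            "cp_from": h.cp_from,
                            "cp_to": h.cp_to,
                        }
                        for h in p.hops
                    ],
                }
                for p in ensemble_paths.paths
            ],
        },
        header,
    )
    # one column per path, residues listed top-down
    longest = max(len(p.residues) for p in ensemble_paths.paths)
    table = {
        f"path_{k + 1} (occ {p.occupancy:.2f})": list(p.residues)
        + [""] * (longest - len(p.residues))
        for k, p in enumerate(ensemble_paths.paths[:10])
    }
    write_tsv(out / "paths.tsv", pd.DataFrame(table), header)
    log.info(
        "pathways: %d distinct paths, top occupancy %.2f",
        len(ensemble_paths.paths), ensemble_paths.paths[0].occupancy,
    )
    result["paths"] = ensemble_paths
    return result


def run_all(config: RunConfig):
    """Full workflow on one alignment + ensemble pair."""
    coevo = run_coevo(config)
    dynamics = run_dynamics(config)
    network = run_network(config, coevo_result=coevo, dynamics_result=dynamics)
    pathways = run_pathways(config, network_result=network)
    return {**coevo, **dynamics, **pathways}
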