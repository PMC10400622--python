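"""End-to-end orchestration: featurize -> label -> curate -> export.

``featurize_pair`` computes all nine residue feature families for one
chain pair and packages them with interface labels into a
:class:`~pairfeat.labeling.PairRecord`:

* geometry: normal vectors, coordination numbers, half-sphere
  compositions, protrusion indices;
* surface: SASA-derived RSA and residue depth, computed once on the
  complex (bound state) and shared between the chains;
* sequence: profile-HMM emission/transition probabilities, mapped from
  per-chain ``.hhm`` files when provided;
* ingest-only annotations: secondary-structure characters and disorder
  propensities/flags from external per-residue tables.

Depth, coordination-number, and protrusion columns are min-max
normalized per structure (jointly over both chains of the pair, so the
complex shares one observed range).  ``run_featurize`` walks a
directory of PDB files, applies the complex-level curation filters,
writes accepted pair records into ``<2nd+3rd PDB id characters>/``
buckets, and returns a manifest of everything written or rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import geometry, labeling, surface
from .curation import CurationCriteria, FilterVerdict, SplitSpec, filter_complex
from .labeling import PairRecord, build_feature_table, find_positive_pairs, sample_negatives
from .profiles import align_profile_to_chain, parse_hhm
from .structure import (
    Chain,
    ChainPair,
    Structure,
    enumerate_chain_pairs,
    first_model,
    read_structure,
    strip_non_standard,
)

__all__ = ["PipelineConfig", "featurize_pair", "run_featurize", "export_graph"]

logger = logging.getLogger("pairfeat")


@dataclass
class PipelineConfig:
    """All tunable parameters of a run; serializable to/from YAML and
    embedded verbatim into every output record's metadata."""

    sasa: surface.SasaParams = field(default_factory=surface.SasaParams)
    significance: geometry.SignificanceParams = field(
        default_factory=geometry.SignificanceParams
    )
    half_sphere: geometry.HalfSphereParams = field(
        default_factory=geometry.HalfSphereParams
    )
    protrusion: geometry.ProtrusionParams = field(
        default_factory=geometry.ProtrusionParams
    )
    criteria: CurationCriteria = field(default_factory=CurationCriteria)
    split: SplitSpec = field(default_factory=SplitSpec)
    contact_threshold: float = 6.0
    contact_mode: str = "heavy_atom"
    interface_water_radius: float = 10.0
    seed: int = 0
    assembly: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        for key, factory in [
            ("sasa", surface.SasaParams),
            ("significance", geometry.SignificanceParams),
            ("half_sphere", geometry.HalfSphereParams),
            ("protrusion", geometry.ProtrusionParams),
            ("criteria", CurationCriteria),
            ("split", SplitSpec),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = factory(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _chain_features(
    chain: Chain,
    all_residues,
    all_atoms,
    sasa_result,
    depths,
    config: PipelineConfig,
    hhm_path: Path | None,
    ss_annotations,
    idr_annotations,
) -> dict:
    residues = [r for r in chain.residues if r.is_standard_aa]
    n = len(residues)
    rsa = np.array([
        surface.relative_solvent_accessibility(r, sasa_result) for r in residues
    ])
    rd_raw = np.array([depths[r.key] for r in residues])
    cn_raw = np.array([
        float(geometry.coordination_number(r, all_residues, config.significance))
        for r in residues
    ])
    pi = np.array([
        geometry.protrusion_index(r, all_atoms, config.protrusion) for r in residues
    ]).reshape(n, 6)
    hs = np.array([
        geometry.hsaac(r, all_residues, config.half_sphere) for r in residues
    ]).reshape(n, 42)
    nv = np.array([geometry.amide_normal_vector(r) for r in residues]).reshape(n, 3)
    ca = np.array([
        r.get_atom("CA").coords if r.get_atom("CA") is not None
        else np.full(3, np.nan)
        for r in residues
    ]).reshape(n, 3)
    if hhm_path is not None:
        profile = align_profile_to_chain(parse_hhm(hhm_path), residues)
    else:
        profile = np.full((n, 27), np.nan)
    ss = None
    if ss_annotations:
        ss = [ss_annotations.get(r.key, "-") for r in residues]
    idr_prop = idr_flag = None
    if idr_annotations:
        idr_prop = np.array([
            idr_annotations.get(r.key, (np.nan, np.nan))[0] for r in residues
        ])
        idr_flag = np.array([
            idr_annotations.get(r.key, (np.nan, np.nan))[1] for r in residues
        ])
    return {
        "rsa": rsa,
        "rd_raw": rd_raw,
        "cn_raw": cn_raw,
        "pi_raw": pi,
        "hsaac": hs,
        "profile": profile,
        "nv": nv,
        "ca_coords": ca,
        "ss": ss,
        "idr_propensity": idr_prop,
        "idr_flag": idr_flag,
    }


def featurize_pair(
    structure: Structure,
    pair: ChainPair,
    config: PipelineConfig | None = None,
    hhm_paths: dict[str, Path] | None = None,
    ss_annotations: dict | None = None,
    idr_annotations: dict | None = None,
    negative_seed: int | None = None,
) -> PairRecord:
    """Compute the full feature set and interface labels for one pair.

    ``hhm_paths`` maps chain ids to ``.hhm`` files; ``ss_annotations``
    and ``idr_annotations`` map residue keys to an SS character and a
    ``(propensity, flag)`` tuple respectively.  The negative-sampling
    seed defaults to ``config.seed + pair.pair_index``.
    """
    if config is None:
        config = PipelineConfig()
    stripped = strip_non_standard(first_model(structure))
    chain_a = stripped.chain(pair.chain_a)
    chain_b = stripped.chain(pair.chain_b)
    pair_atoms = chain_a.heavy_atoms() + chain_b.heavy_atoms()
    all_residues = [
        r for c in (chain_a, chain_b) for r in c.residues if r.is_standard_aa
    ]

    sasa_result = surface.shrake_rupley_sasa(pair_atoms, config.sasa, keep_points=True)
    pair_structure = Structure(pdb_id=stripped.pdb_id, models=[[chain_a, chain_b]])
    depths = surface.residue_depths(pair_structure, surface=sasa_result)

    tables = []
    for chain in (chain_a, chain_b):
        feats = _chain_features(
            chain, all_residues, pair_atoms, sasa_result, depths, config,
            (hhm_paths or {}).get(chain.id), ss_annotations, idr_annotations,
        )
        tables.append((chain, feats))

    # structure-specific min-max normalization, jointly over both chains
    rd_all = surface.minmax_normalize(
        np.concatenate([f["rd_raw"] for _, f in tables])
    )
    cn_all = surface.minmax_normalize(
        np.concatenate([f["cn_raw"] for _, f in tables])
    )
    pi_stack = np.concatenate([f["pi_raw"] for _, f in tables])
    pi_all = np.column_stack([
        surface.minmax_normalize(pi_stack[:, k]) for k in range(6)
    ]) if len(pi_stack) else pi_stack

    frames = []
    offset = 0
    for chain, feats in tables:
        n = len(feats["rsa"])
        frames.append(
            build_feature_table(
                chain,
                rsa=feats["rsa"],
                rd_norm=rd_all[offset:offset + n],
                cn_norm=cn_all[offset:offset + n],
                pi=pi_all[offset:offset + n],
                hsaac=feats["hsaac"],
                profile=feats["profile"],
                nv=feats["nv"],
                ca_coords=feats["ca_coords"],
                ss=feats["ss"],
                idr_propensity=feats["idr_propensity"],
                idr_flag=feats["idr_flag"],
            )
        )
        offset += n

    positives = find_positive_pairs(
        chain_a, chain_b, threshold=config.contact_threshold, mode=config.contact_mode
    )
    if negative_seed is None:
        negative_seed = config.seed + pair.pair_index
    negatives = sample_negatives(
        positives, len(frames[0]), len(frames[1]), seed=negative_seed
    )
    n_atoms = len(pair_atoms)
    metadata = {
        "contact_threshold": config.contact_threshold,
        "contact_mode": config.contact_mode,
        "negative_seed": int(negative_seed),
        "n_atoms": n_atoms,
        "n_residues": len(all_residues),
        "config": config.to_dict(),
    }
    return PairRecord(
        pdb_id=structure.pdb_id,
        chain_ids=(pair.chain_a, pair.chain_b),
        pair_index=pair.pair_index,
        table_0=frames[0],
        table_1=frames[1],
        positives=positives,
        negatives=negatives,
        assembly=config.assembly,
        metadata=metadata,
    )


def run_featurize(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    hhm_dir: str | Path | None = None,
    fmt: str = "hdf5",
) -> dict:
    """Featurize every PDB file in a directory tree.

    For each complex, chain pairs are enumerated on the stripped first
    model, filtered with the complex-level criteria, featurized, and
    written as ``<bucket>/<pdb_id>.pdb<assembly>_<index>.<ext>``.
    Per-file failures are logged and skipped; the returned manifest
    (also written as ``manifest.json``) records every output and every
    reject reason.  A run is deterministic given config and seed.
    """
    if config is None:
        config = PipelineConfig()
    if fmt not in {"hdf5", "pickle"}:
        raise ValueError(f"unknown output format {fmt!r}")
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    hhm_dir = Path(hhm_dir) if hhm_dir is not None else None

    manifest: dict = {"written": [], "rejected": [], "failed": []}
    pdb_files = sorted(input_dir.glob("**/*.pdb"))
    for pdb_file in pdb_files:
        try:
            structure = read_structure(pdb_file)
            stripped = strip_non_standard(first_model(structure))
            if len(stripped.chains) < 2:
                manifest["rejected"].append(
                    {"file": pdb_file.name, "pair": None,
                     "reasons": ["fewer than two chains"]}
                )
                continue
            for pair in enumerate_chain_pairs(stripped):
                verdict: FilterVerdict = filter_complex(
                    stripped, pair, config.criteria, sasa_params=config.sasa
                )
                if not verdict:
                    manifest["rejected"].append(
                        {"file": pdb_file.name, "pair": pair.name(config.assembly),
                         "reasons": verdict.reasons}
                    )
                    continue
                hhm_paths = None
                if hhm_dir is not None:
                    hhm_paths = {
                        cid: p
                        for cid in (pair.chain_a, pair.chain_b)
                        for p in [hhm_dir / f"{pdb_file.stem}_{cid}.hhm"]
                        if p.exists()
                    }
                record = featurize_pair(structure, pair, config, hhm_paths)
                ext = "h5" if fmt == "hdf5" else "pkl"
                out_path = output_dir / record.bucket / f"{record.name}.{ext}"
                if fmt == "hdf5":
                    record.to_hdf5(out_path)
                else:
                    record.to_pickle(out_path)
                manifest["written"].append(
                    {"file": pdb_file.name, "pair": record.name,
                     "path": str(out_path.relative_to(output_dir)),
                     "n_positives": len(record.positives),
                     "n_negatives": len(record.negatives)}
                )
        except Exception as exc:
            logger.error("failed to featurize %s: %s", pdb_file, exc)
            manifest["failed"].append({"file": pdb_file.name, "error": str(exc)})
    manifest["config"] = config.to_dict()
    manifest["n_inputs"] = len(pdb_files)
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if pdb_files and len(manifest["failed"]) == len(pdb_files):
        raise RuntimeError("all input files failed to featurize")
    return manifest


def export_graph(
    record: PairRecord,
    cutoff: float = 15.0,
    path: str | Path | None = None,
):
    """Node-link graph of a pair record.

    Nodes are residues of both tables (ids ``"0:<row>"`` / ``"1:<row>"``)
    carrying their concatenated numeric feature vectors; edges connect
    residues with CA distance <= cutoff and carry the distance and the
    angle between the two amide normal vectors (arccos of the clamped
    dot product of the normalized vectors; NaN when either is NaN).
    Written as node-link JSON when ``path`` is given.
    """
    import networkx as nx

    graph = nx.Graph()
    tables = [record.table_0, record.table_1]
    coords, nvs, ids = [], [], []
    for t_idx, table in enumerate(tables):
        numeric = table[labeling.NUMERIC_FEATURE_COLS].to_numpy(dtype=float)
        ca = table[labeling.CA_COLS].to_numpy(dtype=float)
        nv = table[labeling.NV_COLS].to_numpy(dtype=float)
        for row in range(len(table)):
            node_id = f"{t_idx}:{row}"
            graph.add_node(node_id, table=t_idx, row=row,
                           features=[float(v) for v in numeric[row]])
            coords.append(ca[row])
            nvs.append(nv[row])
            ids.append(node_id)
    coords_arr = np.array(coords)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.any(np.isnan(coords_arr[i])) or np.any(np.isnan(coords_arr[j])):
                continue
            dist = float(np.linalg.norm(coords_arr[i] - coords_arr[j]))
            if dist <= cutoff:
                graph.add_edge(ids[i], ids[j], distance=dist,
                               nv_angle=_nv_angle(nvs[i], nvs[j]))
    if path is not None:
        data = nx.node_link_data(graph, edges="edges")
        Path(path).write_text(json.dumps(data))
    return graph


def _nv_angle(nv_a: np.ndarray, nv_b: np.ndarray) -> float:
    if np.any(np.isnan(nv_a)) or np.any(np.isnan(nv_b)):
        return float("nan")
    norm_a = np.linalg.norm(nv_a)
    norm_b = np.linalg.norm(nv_b)
    if norm_a == 0 or norm_b == 0:
        return float("nan")
    cos = float(np.clip(np.dot(nv_a / norm_a, nv_b / norm_b), -1.0, 1.0))
    return float(np.arccos(cos))
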