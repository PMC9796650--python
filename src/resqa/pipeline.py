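"""End-to-end featurization: from a model plus its companion files to the
network inputs.

The residual-CNN predictor consumes (per-residue 83-column bundle,
neighbour concatenation, neighbour presence mask); the graph predictor
consumes a ``ProteinGraph`` whose nodes carry the 77-column bundle and
whose global features are the six model-level agreement scores.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from . import features, graphbuild, sovscore, structio
from .features import FeatureBundle
from .graphbuild import ProteinGraph
from .structio import ModelStructure

__all__ = ["FeatureSet", "build_parts", "mass2_inputs", "law_inputs",
           "featurize_model", "rsa_to_labels"]

RSA_EXPOSED_THRESHOLD = 0.25


def rsa_to_labels(rsa: np.ndarray) -> str:
    """Binarise relative accessibility into buried/exposed at 25%."""
    return "".join("e" if r >= RSA_EXPOSED_THRESHOLD else "b" for r in rsa)


class FeatureSet(dict):
    """The named category matrices of one model (dict with fixed keys)."""


def build_parts(model: ModelStructure, *, pssm_raw: np.ndarray,
                rosetta_raw: np.ndarray, ss_seq: str, ss_model: str,
                rsa_seq_labels: str, rsa_model_labels: str,
                rsa_model: np.ndarray,
                rosetta_stats: Optional[tuple] = None) -> FeatureSet:
    """Compute all six feature categories for one model."""
    L = len(model)
    sov_local = np.hstack([
        sovscore.local_sov_features(ss_seq, ss_model),
        sovscore.local_sov_features(rsa_seq_labels, rsa_model_labels),
    ])
    sov_global = sovscore.global_sov_features(
        ss_seq, ss_model, rsa_seq_labels, rsa_model_labels)
    return FeatureSet(
        onehot=features.one_hot(model.sequence),
        pssm=features.pssm_features(pssm_raw),
        rosetta=features.rosetta_features(rosetta_raw, rosetta_stats),
        sov_local=sov_local,
        sov_global=sov_global,
        # potentials are extensive (sums over the model); the intensive
        # per-residue form keeps all feature blocks on a comparable scale
        potentials=features.mass_potentials(model, ss_model, rsa_model) / L,
        posenc=features.positional_encoding(L),
    )


def mass2_inputs(model: ModelStructure, parts: FeatureSet
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(per-residue 83-col matrix, 5-neighbour concatenation, mask)."""
    bundle = features.assemble("MASS2", **parts)
    index = graphbuild.nearest_spatial_neighbors(model)
    nc = graphbuild.concat_neighbor_features(bundle, index)
    mask = (index.neighbors != graphbuild.PAD).astype(float)
    return bundle.matrix, nc, mask


def law_inputs(model: ModelStructure, parts: FeatureSet) -> ProteinGraph:
    """Protein graph with 77-column nodes and agreement-score globals."""
    bundle = features.assemble("LAW", **parts)
    return graphbuild.build_graph(model, bundle.matrix,
                                  parts["sov_global"])


def featurize_model(decoy: ModelStructure, feat_dir, method: str,
                    rosetta_stats: Optional[tuple] = None):
    """Read companion files of one decoy and build its network input.

    Expects the layout written by ``synthdata.make_companions``:
    ``<target>.fasta``, ``<target>.pssm``, ``<model>.energies.tsv``,
    ``<model>.labels.fasta`` (ss_seq / ss_model / rsa_seq / rsa_model
    label strings) and ``<model>.rsa.tsv``.
    """
    feat_dir = Path(feat_dir)
    target = decoy.target_id
    L = len(decoy)
    pssm_raw = structio.read_pssm(feat_dir / f"{target}.pssm",
                                  expected_length=L)
    rosetta_raw = structio.read_rosetta_scores(
        feat_dir / f"{decoy.model_id}.energies.tsv")
    labels = structio.read_fasta(feat_dir / f"{decoy.model_id}.labels.fasta")
    rsa_vals = np.loadtxt(feat_dir / f"{decoy.model_id}.rsa.tsv",
                          skiprows=1)
    parts = build_parts(
        decoy, pssm_raw=pssm_raw, rosetta_raw=rosetta_raw,
        ss_seq=labels["ss_seq"], ss_model=labels["ss_model"],
        rsa_seq_labels=labels["rsa_seq"],
        rsa_model_labels=labels["rsa_model"],
        rsa_model=rsa_vals[:, 1], rosetta_stats=rosetta_stats)
    if method.upper() == "MASS2":
        return mass2_inputs(decoy, parts)
    if method.upper() == "LAW":
        return law_inputs(decoy, parts)
    raise ValueError("method must be MASS2 or LAW")
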