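"""Per-residue feature extraction and assembly.

Six feature categories feed the predictors:

* one-hot amino-acid encoding (L x 21; 21st column = non-canonical),
* PSSM log-odds, squashed to (0, 1) (L x 20),
* normalised Rosetta REF15 energies with their row sum appended (L x 20),
* windowed secondary-structure / solvent-accessibility agreement scores
  (Q3, SOV'99, SOV_refine for each; L x 6),
* global versions of the same six agreement scores (1 x 6),
* six model-level statistical potentials (1 x 6),
* sinusoidal positional encoding (L x 4).

The residual-CNN predictor consumes all blocks with the global agreement
scores duplicated on every row (83 columns); the graph-network predictor
keeps the global scores as graph-level features, so its node matrix omits
that block (77 columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .structio import ModelStructure

__all__ = [
    "AA_ORDER", "FeatureBundle", "one_hot", "positional_encoding",
    "pssm_features", "rosetta_features", "mass_potentials", "assemble",
    "MASS2_BLOCKS", "LAW_BLOCKS",
]

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

MASS2_BLOCKS = [("onehot", 21), ("pssm", 20), ("rosetta", 20),
                ("sov_local", 6), ("sov_global", 6), ("potentials", 6),
                ("posenc", 4)]
LAW_BLOCKS = [("onehot", 21), ("pssm", 20), ("rosetta", 20),
              ("sov_local", 6), ("potentials", 6), ("posenc", 4)]


@dataclass
class FeatureBundle:
    """An (L, D) feature matrix with named, contiguous column blocks."""

    matrix: np.ndarray
    blocks: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        widths = sum(w for _, w in self.blocks)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != widths:
            raise ValueError(
                f"matrix width {self.matrix.shape[1]} != declared block sum "
                f"{widths}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def block(self, name: str) -> np.ndarray:
        """Column slice of one named block."""
        lo = 0
        for bname, w in self.blocks:
            if bname == name:
                return self.matrix[:, lo:lo + w]
            lo += w
        raise KeyError(name)

    def save_npz(self, path) -> None:
        np.savez(path, matrix=self.matrix,
                 block_names=np.array([b for b, _ in self.blocks]),
                 block_widths=np.array([w for _, w in self.blocks]))

    @classmethod
    def load_npz(cls, path) -> "FeatureBundle":
        with np.load(path, allow_pickle=False) as z:
            blocks = list(zip([str(s) for s in z["block_names"]],
                              [int(w) for w in z["block_widths"]]))
            return cls(matrix=z["matrix"], blocks=blocks)


def one_hot(sequence: str) -> np.ndarray:
    """Encode an amino-acid string as an (L, 21) indicator matrix.

    Column 21 catches every letter outside the 20 canonical residues, so
    every row sums to exactly 1.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    out = np.zeros((len(sequence), 21))
    for i, aa in enumerate(sequence.upper()):
        j = AA_ORDER.find(aa)
        out[i, j if j >= 0 else 20] = 1.0
    return out


def positional_encoding(L: int) -> np.ndarray:
    """Sinusoidal position features: (sin p, cos p, sin p/100, cos p/100)
    for p = 1..L, in radians."""
    if L < 1:
        raise ValueError("L must be >= 1")
    pos = np.arange(1, L + 1, dtype=float)
    return np.column_stack([np.sin(pos), np.cos(pos),
                            np.sin(pos / 100.0), np.cos(pos / 100.0)])


def pssm_features(pssm: np.ndarray) -> np.ndarray:
    """Bound raw PSSM log-odds: sigmoid(score / 10)."""
    pssm = np.asarray(pssm, dtype=float)
    return 1.0 / (1.0 + np.exp(-pssm / 10.0))


def rosetta_features(raw: np.ndarray,
                     stats: Optional[tuple[np.ndarray, np.ndarray]] = None
                     ) -> np.ndarray:
    """Append the 19-term row sum as a 20th energy, then z-score each column.

    ``stats`` is an optional (mean, sd) pair of length-20 vectors saved from
    a training corpus; without it the model's own column statistics are used.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 19:
        raise ValueError("raw Rosetta table must be (L, 19)")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite Rosetta energy")
    full = np.column_stack([raw, raw.sum(axis=1)])
    if stats is None:
        mean = full.mean(axis=0)
        sd = full.std(axis=0)
    else:
        mean, sd = (np.asarray(v, dtype=float) for v in stats)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (full - mean) / sd


# ---------------------------------------------------------------------------
# Statistical potentials
# ---------------------------------------------------------------------------

_HYDROPHOBIC = set("AVLIMFWYC")
_CHARGED = set("DEKRH")
_EPS = 1e-4


def _aa_class(aa: str) -> str:
    if aa in _HYDROPHOBIC:
        return "h"
    if aa in _CHARGED:
        return "c"
    return "p"


@lru_cache(maxsize=1)
def _tables() -> dict:
    with resources.files("resqa.data").joinpath(
            "potential_tables.json").open() as fh:
        return json.load(fh)


def pseudo_bond_angles(coords: np.ndarray) -> np.ndarray:
    """Calpha pseudo-bond angles in degrees at residues 2..L-1 (1-based)."""
    coords = np.asarray(coords, dtype=float)
    v1 = coords[:-2] - coords[1:-1]
    v2 = coords[2:] - coords[1:-1]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _neglog_ratio(p_obs: np.ndarray, p_ref: np.ndarray) -> np.ndarray:
    return -np.log((np.asarray(p_obs) + _EPS) / (np.asarray(p_ref) + _EPS))


def mass_potentials(model: ModelStructure, ss: str,
                    rsa: np.ndarray) -> np.ndarray:
    """Six model-level statistical-potential scores.

    Each is a sum of -log frequency-ratio terms scoring the model's geometry
    against reference frequency tables estimated from an ensemble of
    ideal-geometry structures (shipped as package data): pseudo-bond-angle,
    burial (accessible-surface proxy), sequence-separation-dependent pair
    distances, contact class preferences, relative-solvent-accessibility
    preferences, and local packing volume.  Lower = more native-like.
    Deterministic; broadcast to every residue row when features are
    assembled.
    """
    L = len(model)
    if L < 4:
        raise ValueError("need >= 4 residues for pseudo-bond angles")
    if len(ss) != L or len(rsa) != L:
        raise ValueError("ss and rsa must match model length")
    rsa = np.asarray(rsa, dtype=float)
    T = _tables()
    coords = model.coords
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

    # 1. pseudo-bond angle, conditioned on the central residue's SS state
    ang = pseudo_bond_angles(coords)
    nbins = T["angle"]["bins"]
    idx = np.minimum((ang / 180.0 * nbins).astype(int), nbins - 1)
    s_angle = 0.0
    for k, b in enumerate(idx):
        cond = T["angle"]["cond"].get(ss[k + 1], T["angle"]["ref"])
        s_angle += _neglog_ratio(cond[b], 1.0 / nbins)

    # 2. burial / accessible-surface proxy: neighbour count within 10 A,
    #    conditioned on hydrophobicity class
    nb10 = (dmat < 10.0).sum(axis=1) - 1
    edges = np.asarray(T["burial"]["edges"])
    bins = np.clip(np.searchsorted(edges, nb10, side="right") - 1,
                   0, len(edges) - 2)
    s_burial = 0.0
    nref = len(edges) - 1
    for i in range(L):
        cond = T["burial"]["cond"][_aa_class(model.sequence[i])]
        s_burial += _neglog_ratio(cond[bins[i]], 1.0 / nref)

    # 3. sequence-separation-dependent distance potential
    dist_edges = np.asarray(T["sepdist"]["dist_edges"])
    ndist = len(dist_edges) - 1
    s_sep = 0.0
    for sep_name, lo, hi in (("short", 7, 12), ("medium", 12, 24),
                             ("long", 24, 10 ** 9)):
        cond = T["sepdist"]["cond"][sep_name]
        ii, jj = np.triu_indices(L, k=lo)
        keep = (jj - ii) < hi
        d = dmat[ii[keep], jj[keep]]
        d = d[d < dist_edges[-1]]
        if len(d) == 0:
            continue
        db = np.clip(np.searchsorted(dist_edges, d, side="right") - 1,
                     0, ndist - 1)
        s_sep += float(np.sum(_neglog_ratio(np.asarray(cond)[db],
                                            1.0 / ndist)))

    # 4. contact-dependent potential: class-pair preferences among contacts
    pair_tab = T["contact"]["pair"]
    ii, jj = np.where(np.triu(dmat < 8.0, k=3))
    s_contact = 0.0
    comp = {"h": 0.0, "p": 0.0, "c": 0.0}
    for aa in model.sequence:
        comp[_aa_class(aa)] += 1.0 / L
    for a, b in zip(ii, jj):
        ca, cb = sorted((_aa_class(model.sequence[a]),
                         _aa_class(model.sequence[b])))
        expect = comp[ca] * comp[cb] * (2.0 if ca != cb else 1.0)
        s_contact += float(_neglog_ratio(pair_tab[ca + cb], expect))

    # 5. relative solvent accessibility potential
    nrsa = T["rsa"]["bins"]
    rb = np.minimum((rsa * nrsa).astype(int), nrsa - 1)
    s_rsa = 0.0
    for i in range(L):
        cond = T["rsa"]["cond"][_aa_class(model.sequence[i])]
        s_rsa += _neglog_ratio(cond[rb[i]], 1.0 / nrsa)

    # 6. volume-dependent potential: local packing via 6.5-A neighbour count
    nb65 = (dmat < 6.5).sum(axis=1) - 1
    vedges = np.asarray(T["volume"]["edges"])
    vb = np.clip(np.searchsorted(vedges, nb65, side="right") - 1,
                 0, len(vedges) - 2)
    probs = np.asarray(T["volume"]["probs"])
    s_vol = float(np.sum(_neglog_ratio(probs[vb], 1.0 / len(probs))))

    out = np.array([s_angle, s_burial, s_sep, s_contact, s_rsa, s_vol],
                   dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite potential score")
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(method: str, *, onehot: np.ndarray, pssm: np.ndarray,
             rosetta: np.ndarray, sov_local: np.ndarray,
             sov_global: np.ndarray, potentials: np.ndarray,
             posenc: np.ndarray) -> FeatureBundle:
    """Concatenate the category matrices into one feature bundle.

    ``method`` is ``"MASS2"`` (83 columns; the global agreement scores are
    duplicated on every row) or ``"LAW"`` (77-column node matrix; global
    scores live on the graph instead).  Row-level parts must share L;
    ``sov_global`` and ``potentials`` are length-6 vectors broadcast to L.
    """
    method = method.upper()
    if method not in ("MASS2", "LAW"):
        raise ValueError("method must be MASS2 or LAW")
    L = onehot.shape[0]
    sov_global = np.broadcast_to(np.asarray(sov_global, dtype=float), (L, 6))
    potentials = np.broadcast_to(np.asarray(potentials, dtype=float), (L, 6))
    parts = {"onehot": onehot, "pssm": pssm, "rosetta": rosetta,
             "sov_local": sov_local, "sov_global": sov_global,
             "potentials": potentials, "posenc": posenc}
    blocks = MASS2_BLOCKS if method == "MASS2" else LAW_BLOCKS
    cols = []
    for name, width in blocks:
        m = np.asarray(parts[name], dtype=float)
        if m.shape != (L, width):
            raise ValueError(
                f"block '{name}' has shape {m.shape}, expected ({L}, {width})")
        cols.append(m)
    return FeatureBundle(matrix=np.hstack(cols), blocks=list(blocks))
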