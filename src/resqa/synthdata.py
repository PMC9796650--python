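"""Synthetic targets, decoy models and companion feature files.

Every other module is testable offline through this generator.  Natives are
ideal-geometry Calpha traces (helix: 1.5 A rise per residue with a 100 deg
turn on a 2.3 A radius; strand: 3.3 A rise with an alternating pleat; coil:
a direction-correlated random walk with 3.8 A virtual bonds).  Decoys apply
a random rigid motion, segment-wise Gaussian coordinate noise, and forced
large displacements on a designated fraction of residues, so a decoy pool
spans the full range of global quality.  True per-residue deviations are
recomputed with the toolkit's own Kabsch superposition, never taken from
the construction noise, so the generator and the evaluator cannot
disagree.

What this emulates — and what it does not: the pools have realistic local
error structure (contiguous bad segments, graded noise) and companion
features carrying genuine signal (PSSM peaked on the true residue, energy
columns increasing with local deviation), but the decoys are not physically
realistic conformations and carry no side chains.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import structio
from .structio import DeviationProfile, ModelStructure, QaPrediction

__all__ = ["SynthSpec", "make_native", "make_decoys", "make_companions",
           "make_group_predictions", "assign_ss_rsa", "write_synth_tree"]

_AA = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SynthSpec:
    """Study conditions for one synthetic target.

    ``ss_layout`` is a list of (state, length) segments, e.g.
    [("H", 20), ("C", 8), ("E", 12), ...]; ``noise_sds`` gives the
    per-decoy Gaussian coordinate noise (A), one entry per decoy;
    ``forced_fraction`` is the fraction of residues pushed beyond the
    3.8 A accuracy threshold in each decoy (as one contiguous segment per
    ~15 affected residues, displacement ~8 A).
    """

    seed: int = 0
    length: int = 60
    ss_layout: Optional[list[tuple[str, int]]] = None
    n_decoys: int = 30
    noise_sds: Optional[Sequence[float]] = None
    forced_fraction: float = 0.15
    target_id: str = "S0001"

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError("length must be >= 10")
        if not 0.0 <= self.forced_fraction <= 1.0:
            raise ValueError("forced_fraction in [0, 1]")
        if self.ss_layout is None:
            # default: helix - coil - strand - coil - helix proportional mix
            L = self.length
            h1 = max(6, int(0.3 * L)); e1 = max(4, int(0.2 * L))
            c1 = max(3, int(0.1 * L)); h2 = max(6, int(0.25 * L))
            c2 = L - h1 - e1 - c1 - h2
            if c2 < 3:
                c2 = 3
                h2 = L - h1 - e1 - c1 - c2
            self.ss_layout = [("H", h1), ("C", c1), ("E", e1), ("C", c2),
                              ("H", h2)]
        if sum(n for _, n in self.ss_layout) != self.length:
            raise ValueError("ss_layout lengths must sum to length")
        if self.noise_sds is None:
            # graded pool: near-perfect decoys through heavily damaged ones
            self.noise_sds = list(np.linspace(0.05, 3.0, self.n_decoys))
        if len(self.noise_sds) != self.n_decoys:
            raise ValueError("need one noise sd per decoy")
        if any(s < 0 for s in self.noise_sds):
            raise ValueError("noise sds must be >= 0")

    @property
    def ss_string(self) -> str:
        return "".join(state * n for state, n in self.ss_layout)


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def make_native(spec: SynthSpec) -> ModelStructure:
    """Deterministic ideal-geometry Calpha trace for the layout in ``spec``.

    Consecutive Calpha distances are 3.8 +/- 0.1 A in every state.
    """
    rng = np.random.default_rng(spec.seed)
    coords: list[np.ndarray] = []
    direction = np.array([1.0, 0.0, 0.0])
    for state, n in spec.ss_layout:
        frame = _frame_from_direction(direction)
        if state == "C":
            # correlated random walk, exact 3.8 A steps
            for _ in range(n):
                step = direction + 0.6 * rng.normal(size=3)
                step /= np.linalg.norm(step)
                prev = coords[-1] if coords else np.zeros(3) - 3.8 * step
                coords.append(prev + 3.8 * step)
                direction = step
        else:
            if state == "H":
                radius, rise, turn = 2.3, 1.5, math.radians(100.0)
                local = np.array([
                    [k * rise, radius * math.cos(k * turn),
                     radius * math.sin(k * turn)] for k in range(n)])
            else:  # strand: 3.3 A rise with an alternating pleat
                local = np.array([[k * 3.3, 0.95 * (-1) ** k, 0.0]
                                  for k in range(n)])
            pts = local @ frame.T
            # rigid placement: first residue lands one 3.8 A bond ahead of
            # the previous one, preserving ideal intra-segment geometry
            prev = coords[-1] if coords else -3.8 * direction
            pts = pts + (prev + 3.8 * direction - pts[0])
            coords.extend(pts)
            if n >= 2:
                direction = pts[-1] - pts[-2]
                direction /= np.linalg.norm(direction)
        # turn the chain between segments so it does not run straight off
        direction = _rotation(rng.normal(size=3),
                              rng.uniform(0.5, 1.5)) @ direction
    coords = np.asarray(coords[:spec.length])
    seq = "".join(rng.choice(list(_AA), size=spec.length))
    return ModelStructure(
        model_id=f"{spec.target_id}_native", target_id=spec.target_id,
        seq_index=np.arange(1, spec.length + 1), sequence=seq,
        coords=coords)


def _frame_from_direction(direction: np.ndarray) -> np.ndarray:
    """Orthonormal frame with the first axis along ``direction``."""
    x = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(x, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    y = np.cross(x, helper)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def make_decoys(native: ModelStructure, spec: SynthSpec
                ) -> list[tuple[ModelStructure, DeviationProfile]]:
    """Decoy pool with controlled damage and self-consistent deviations."""
    rng = np.random.default_rng(spec.seed + 1)
    L = len(native)
    out = []
    for d in range(spec.n_decoys):
        coords = native.coords.copy()
        sd = spec.noise_sds[d]
        # segment-wise noise: smooth magnitude profile per SS segment
        lo = 0
        for state, n in spec.ss_layout:
            seg_scale = sd * rng.uniform(0.5, 1.5)
            coords[lo:lo + n] += rng.normal(scale=max(seg_scale, 1e-12),
                                            size=(n, 3))
            lo += n
        # forced inaccurate contiguous segments (~8-10 A displacement);
        # graded across the pool (0 .. 2x the spec fraction, mean = spec
        # fraction) so the pool spans near-perfect to heavily damaged
        ramp = 2.0 * d / max(spec.n_decoys - 1, 1)
        n_forced = int(round(spec.forced_fraction * ramp * L))
        placed = 0
        while placed < n_forced:
            seg_len = min(int(rng.integers(4, 16)), n_forced - placed)
            start = int(rng.integers(0, max(1, L - seg_len)))
            shift = rng.normal(size=3)
            shift = shift / np.linalg.norm(shift) * rng.uniform(8.0, 10.0)
            coords[start:start + seg_len] += shift
            placed += seg_len
        # random rigid motion of the whole decoy
        R = _rotation(rng.normal(size=3), rng.uniform(0, 2 * math.pi))
        t = rng.uniform(-20, 20, size=3)
        coords = coords @ R.T + t
        decoy = ModelStructure(
            model_id=f"{native.target_id}_decoy{d + 1:03d}",
            target_id=native.target_id,
            seq_index=native.seq_index.copy(), sequence=native.sequence,
            coords=coords)
        profile = structio.superpose_kabsch(decoy, native)
        out.append((decoy, profile))
    return out


def assign_ss_rsa(spec: SynthSpec, model: ModelStructure,
                  profile: Optional[DeviationProfile] = None,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[str, np.ndarray]:
    """Model-derived SS labels and RSA values.

    The native layout supplies the baseline; residues displaced beyond the
    accuracy threshold flip to coil with shuffled RSA, which makes the
    model-based label strings disagree with sequence-based ones exactly
    where the model is wrong.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    ss = list(spec.ss_string)
    # burial proxy from geometry: neighbour count within 10 A
    d = np.linalg.norm(model.coords[:, None] - model.coords[None, :],
                       axis=2)
    nb = (d < 10.0).sum(axis=1) - 1
    rsa = np.clip(1.0 - nb / max(nb.max(), 1), 0.0, 1.0)
    if profile is not None:
        bad = np.isfinite(profile.deviations) & (profile.deviations >= 3.8)
        for i in np.where(bad)[0]:
            ss[i] = "C" if rng.random() < 0.8 else ss[i]
            rsa[i] = rng.uniform(0, 1)
    return "".join(ss), rsa


def make_companions(native: ModelStructure, decoy: ModelStructure,
                    profile: DeviationProfile, out_dir,
                    spec: SynthSpec) -> dict[str, Path]:
    """Write FASTA / PSSM / Rosetta-table / SS+RSA label files for a decoy.

    Files use the exact dialects the structio readers consume.  The PSSM is
    peaked on the true residue identity; the energy columns increase with
    local deviation so the features carry learnable signal.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(
        spec.seed + 7 + zlib.crc32(decoy.model_id.encode()) % 100000)
    L = len(native)
    paths: dict[str, Path] = {}

    fasta = out_dir / f"{native.target_id}.fasta"
    structio.write_fasta({native.target_id: native.sequence}, fasta)
    paths["fasta"] = fasta

    pssm_path = out_dir / f"{native.target_id}.pssm"
    with open(pssm_path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(_AA) + "\n")
        for i, aa in enumerate(native.sequence, start=1):
            row = rng.integers(-4, 3, size=20)
            j = _AA.find(aa)
            if j >= 0:
                row[j] = 7 + int(rng.integers(0, 3))
                if rng.random() < 0.1:   # controlled identity noise
                    row[j] = int(rng.integers(-2, 3))
            fh.write(f"{i:5d} {aa} " + " ".join(f"{v:3d}" for v in row)
                     + "\n")
    paths["pssm"] = pssm_path

    ros_path = out_dir / f"{decoy.model_id}.energies.tsv"
    dev = np.nan_to_num(profile.deviations, nan=8.0)
    with open(ros_path, "w") as fh:
        cols = [f"e{k + 1}" for k in range(19)]
        fh.write("res " + " ".join(cols) + "\n")
        for i in range(L):
            base = rng.normal(scale=0.5, size=19)
            base += 0.25 * dev[i] * rng.uniform(0.5, 1.5, size=19)
            fh.write(f"{i + 1} " + " ".join(f"{v:.4f}" for v in base) + "\n")
    paths["rosetta"] = ros_path

    # sequence-based (native layout) and model-based label strings
    ss_seq, rsa_seq = spec.ss_string, None
    d = np.linalg.norm(native.coords[:, None] - native.coords[None, :],
                       axis=2)
    nb = (d < 10.0).sum(axis=1) - 1
    rsa_seq = np.clip(1.0 - nb / max(nb.max(), 1), 0.0, 1.0)
    ss_mod, rsa_mod = assign_ss_rsa(spec, decoy, profile, rng)
    lbl = out_dir / f"{decoy.model_id}.labels.fasta"
    structio.write_fasta({
        "ss_seq": ss_seq,
        "ss_model": ss_mod,
        "rsa_seq": "".join("e" if r >= 0.25 else "b" for r in rsa_seq),
        "rsa_model": "".join("e" if r >= 0.25 else "b" for r in rsa_mod),
    }, lbl)
    paths["labels"] = lbl
    np.savetxt(out_dir / f"{decoy.model_id}.rsa.tsv",
               np.column_stack([rsa_seq, rsa_mod]), fmt="%.4f",
               header="rsa_seq rsa_model")
    paths["rsa"] = out_dir / f"{decoy.model_id}.rsa.tsv"

    dssp_path = out_dir / f"{decoy.model_id}.dssp"
    acc = [int(round(r * structio.MAX_ASA.get(aa, 200.0)))
           for aa, r in zip(decoy.sequence, rsa_mod)]
    write_dssp(dssp_path, decoy.sequence, ss_mod, acc)
    paths["dssp"] = dssp_path
    return paths


def write_dssp(path, sequence: str, ss8: str, acc: Sequence[int],
               chain: str = "A") -> None:
    """Write a DSSP-format file (the fixed-column dialect standard DSSP
    emits) carrying 8-state SS codes and absolute accessibilities."""
    def line(i: int, aa: str, ss: str, a: int) -> str:
        chars = [" "] * 120
        def put(s: str, start: int) -> None:
            for k, c in enumerate(s):
                chars[start + k] = c
        put(f"{i:5d}", 0)
        put(f"{i:5d}", 5)
        put(chain, 11)
        put(aa, 13)
        put(ss if ss != "C" else "-", 16)
        put(f"{a:4d}", 34)
        put(f"{0:7d}", 38); put(f"{0.0:4.1f}", 46)
        put(f"{0:6d}", 50); put(f"{0.0:4.1f}", 57)
        put(f"{0:6d}", 61); put(f"{0.0:4.1f}", 68)
        put(f"{0:6d}", 72); put(f"{0.0:4.1f}", 79)
        put(f"{0.0:6.1f}", 103); put(f"{0.0:6.1f}", 109)
        return "".join(chars).rstrip()

    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition ====\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O"
                 "    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA"
                 " ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n")
        for i, (aa, ss, a) in enumerate(zip(sequence, ss8, acc), start=1):
            fh.write(line(i, aa, ss, int(a)) + "\n")


def make_group_predictions(pool: list[tuple[ModelStructure,
                                            DeviationProfile]],
                           n_groups: int = 5,
                           noise_sds: Optional[Sequence[float]] = None,
                           seed: int = 0) -> dict[str, list[QaPrediction]]:
    """Per-group QA predictions with strictly increasing noise.

    Group g predicts true deviation + N(0, sigma_g) (clipped at 0), sigma
    strictly increasing in g, so a correct evaluation must rank the groups
    in inverse noise order.
    """
    if noise_sds is None:
        noise_sds = [0.0] + list(np.linspace(0.8, 4.0, n_groups - 1))
    if len(noise_sds) != n_groups:
        raise ValueError("need one noise sd per group")
    if np.any(np.diff(noise_sds) <= 0):
        raise ValueError("noise sds must be strictly increasing")
    rng = np.random.default_rng(seed)
    out: dict[str, list[QaPrediction]] = {}
    for g in range(n_groups):
        name = f"G{g + 1:02d}"
        preds = []
        for decoy, profile in pool:
            true = profile.deviations
            noisy = np.clip(true + rng.normal(scale=noise_sds[g] + 1e-12,
                                              size=true.shape), 0.0, None)
            noisy[~np.isfinite(true)] = np.nan
            preds.append(QaPrediction(
                target_id=decoy.target_id, model_id=decoy.model_id,
                local=noisy))
        out[name] = preds
    return out


def write_synth_tree(root, specs: Sequence[SynthSpec],
                     n_groups: int = 5, seed: int = 0) -> dict:
    """Emit a full synthetic study directory: natives/, decoys/, features/,
    qa_groups/, eu_table.tsv, gdt_table.tsv.  Returns a manifest dict."""
    root = Path(root)
    (root / "natives").mkdir(parents=True, exist_ok=True)
    (root / "decoys").mkdir(exist_ok=True)
    (root / "qa_groups").mkdir(exist_ok=True)
    eu_rows, gdt_rows = [], []
    manifest = {"targets": []}
    for spec in specs:
        native = make_native(spec)
        structio.write_pdb_ca(native, root / "natives" /
                              f"{spec.target_id}.pdb")
        pool = make_decoys(native, spec)
        feat_dir = root / "features" / spec.target_id
        for decoy, profile in pool:
            structio.write_pdb_ca(decoy, root / "decoys" /
                                  f"{decoy.model_id}.pdb")
            make_companions(native, decoy, profile, feat_dir, spec)
            gdt = structio.gdt_ts_simple(decoy, native)
            gdt_rows.append((spec.target_id, decoy.model_id, gdt))
        eu_rows.append((f"{spec.target_id}-D1", spec.target_id, 1,
                        spec.length))
        groups = make_group_predictions(pool, n_groups=n_groups,
                                        seed=seed + spec.seed)
        for gname, preds in groups.items():
            gdir = root / "qa_groups" / gname
            gdir.mkdir(exist_ok=True)
            structio.write_casp_qa(preds, gdir / f"{spec.target_id}.qa")
        manifest["targets"].append(spec.target_id)
    with open(root / "eu_table.tsv", "w") as fh:
        fh.write("eu\ttarget\tstart\tend\n")
        for row in eu_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(root / "gdt_table.tsv", "w") as fh:
        fh.write("target\tmodel\tgdt_ts\n")
        for t, m, g in gdt_rows:
            fh.write(f"{t}\t{m}\t{g:.3f}\n")
    return manifest
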