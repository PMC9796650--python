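"""Readers/writers for the external formats the toolkit touches, plus
model-vs-reference deviations.

Formats covered: PDB (ATOM records, Calpha only), CASP QA prediction format
(PFRMAT QA / TARGET / MODEL / per-residue lists / END), PSI-BLAST ASCII PSSM,
DSSP output, whitespace-delimited per-residue Rosetta energy tables, FASTA.

Deviations between a model and a reference structure come from a single
all-residue least-squares (Kabsch) superposition of the shared Calpha sets;
the simplified GDT_TS is computed from the same superposition.  These numbers
are deterministic and dependency-free but not bit-comparable with CASP's LGA
output, which uses iterative fragment superpositions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelStructure",
    "DeviationProfile",
    "QaPrediction",
    "ParseError",
    "read_pdb_ca",
    "write_pdb_ca",
    "read_casp_qa",
    "write_casp_qa",
    "read_pssm",
    "read_dssp_labels",
    "read_rosetta_scores",
    "read_fasta",
    "write_fasta",
    "superpose_kabsch",
    "gdt_ts_simple",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# Sander/Rost maximal accessible surface areas (A^2) used to turn DSSP's
# absolute accessibility into relative solvent accessibility.
MAX_ASA = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ModelStructure:
    """Ordered Calpha trace of one predicted (or native) structure.

    ``bfactors`` may carry per-residue predicted deviations in Angstroms, the
    convention CASP uses for the PDB temperature-factor field.
    """

    model_id: str
    target_id: str
    seq_index: np.ndarray          # (L,) int, 1-based author numbering
    sequence: str                  # one-letter codes, length L
    coords: np.ndarray             # (L, 3) float Calpha coordinates, Angstrom
    bfactors: Optional[np.ndarray] = None   # (L,) float or None

    def __post_init__(self) -> None:
        self.seq_index = np.asarray(self.seq_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        L = len(self.seq_index)
        if L < 1:
            raise ValueError("structure must contain at least one residue")
        if self.coords.shape != (L, 3):
            raise ValueError("coords must be (L, 3)")
        if len(self.sequence) != L:
            raise ValueError("sequence length must match residue count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite Calpha coordinate")
        if np.any(np.diff(self.seq_index) <= 0):
            raise ValueError("seq_index must be strictly increasing")
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if self.bfactors.shape != (L,):
                raise ValueError("bfactors must be length L")

    def __len__(self) -> int:
        return len(self.seq_index)

    def bfactor_profile(self) -> "DeviationProfile":
        """Interpret the temperature-factor column as predicted deviations."""
        if self.bfactors is None:
            raise ValueError(f"{self.model_id}: no temperature factors present")
        return DeviationProfile(
            seq_index=self.seq_index.copy(),
            deviations=self.bfactors.copy(),
            provenance="parsed",
        )


@dataclass
class DeviationProfile:
    """Per-residue distances (A) between a model and a reference.

    ``deviations`` is aligned with ``seq_index``; NaN marks residues with no
    counterpart in the reference.  ``provenance`` records whether the values
    were computed by superposition or parsed from a file.
    """

    seq_index: np.ndarray
    deviations: np.ndarray
    provenance: str = "computed"

    def __post_init__(self) -> None:
        self.seq_index = np.asarray(self.seq_index, dtype=int)
        self.deviations = np.asarray(self.deviations, dtype=float)
        if self.seq_index.shape != self.deviations.shape:
            raise ValueError("seq_index and deviations must align")
        present = self.deviations[~np.isnan(self.deviations)]
        if np.any(present < 0) or np.any(~np.isfinite(present)):
            raise ValueError("deviations must be finite and >= 0")
        if self.provenance not in ("computed", "parsed"):
            raise ValueError("provenance must be 'computed' or 'parsed'")

    def __len__(self) -> int:
        return len(self.seq_index)


@dataclass
class QaPrediction:
    """One MODEL block of a CASP QA submission.

    ``local`` holds per-residue values with NaN for 'X' placeholders; the
    ``is_sscore`` flag records whether those values are S-scores in [0, 1]
    (score-style groups) instead of deviations in Angstroms.
    """

    target_id: str
    model_id: str
    local: np.ndarray
    global_score: Optional[float] = None
    is_sscore: bool = False

    def __post_init__(self) -> None:
        self.local = np.asarray(self.local, dtype=float)
        present = self.local[~np.isnan(self.local)]
        if np.any(present < 0):
            raise ValueError("local QA values must be >= 0")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb_ca(path, chain: Optional[str] = None,
                model_id: Optional[str] = None,
                target_id: str = "") -> ModelStructure:
    """Read the Calpha trace of a PDB file.

    Only ``ATOM`` records with atom name CA are consumed; altloc indicators
    other than blank or 'A' are ignored.  Unless ``chain`` is given, only the
    first chain encountered is read (CASP evaluation units are single-chain).

    Raises
    ------
    ParseError
        If no Calpha atoms are found, or a (chain, resseq, icode) key carries
        more than one Calpha.
    """
    path = Path(path)
    seq_index, seq, coords, bfactors = [], [], [], []
    seen: set = set()
    picked_chain = chain
    any_bfac = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break  # first NMR/multi-model entry only
            if not line.startswith("ATOM"):
                continue
            if line[12:16].strip() != "CA":
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            ch = line[21]
            if picked_chain is None:
                picked_chain = ch
            if ch != picked_chain:
                continue
            resseq = int(line[22:26])
            icode = line[26].strip()
            key = (ch, resseq, icode)
            if key in seen:
                raise ParseError(
                    f"{path.name}: duplicate Calpha for residue "
                    f"{ch}{resseq}{icode}")
            seen.add(key)
            resname = line[17:20].strip()
            seq.append(THREE_TO_ONE.get(resname, "X"))
            seq_index.append(resseq)
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
            bstr = line[60:66].strip()
            if bstr:
                any_bfac = True
                bfactors.append(float(bstr))
            else:
                bfactors.append(np.nan)
    if not seq_index:
        raise ParseError(f"{path.name}: no Calpha ATOM records found")
    order = np.argsort(np.asarray(seq_index), kind="stable")
    seq_index = np.asarray(seq_index)[order]
    if np.any(np.diff(seq_index) == 0):
        raise ParseError(f"{path.name}: duplicate residue numbers in chain")
    return ModelStructure(
        model_id=model_id or path.stem,
        target_id=target_id,
        seq_index=seq_index,
        sequence="".join(np.asarray(list("".join(seq)))[order]),
        coords=np.asarray(coords)[order],
        bfactors=np.asarray(bfactors)[order] if any_bfac else None,
    )


def write_pdb_ca(structure: ModelStructure, path, chain: str = "A") -> None:
    """Write a Calpha-only PDB file (one ATOM record per residue)."""
    with open(path, "w") as fh:
        for k in range(len(structure)):
            aa3 = ONE_TO_THREE.get(structure.sequence[k], "UNK")
            x, y, z = structure.coords[k]
            b = 0.0
            if structure.bfactors is not None and np.isfinite(structure.bfactors[k]):
                b = structure.bfactors[k]
            fh.write(
                f"ATOM  {k + 1:5d}  CA  {aa3} {chain}{structure.seq_index[k]:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                f"           C\n")
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# CASP QA format
# ---------------------------------------------------------------------------

def read_casp_qa(path) -> list[QaPrediction]:
    """Parse a CASP QA submission into one QaPrediction per MODEL block.

    Expected layout::

        PFRMAT QA
        TARGET T1234
        MODEL 1
        servername_TS1 0.82 1.2 3.4 X 0.9 ...
        END

    Per-residue values run until END or the next MODEL line; 'X' placeholders
    become NaN.  The first numeric token after the model name is the global
    score ('X' allowed).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    target = None
    saw_pfrmat = False
    preds: list[QaPrediction] = []
    current_tokens: list[str] = []

    def flush() -> None:
        if not current_tokens:
            return
        name = current_tokens[0]
        vals = current_tokens[1:]
        if not vals:
            raise ParseError(f"{path.name}: MODEL block '{name}' has no values")
        def conv(tok: str) -> float:
            if tok.upper() == "X":
                return np.nan
            return float(tok)
        glob = conv(vals[0])
        local = np.array([conv(t) for t in vals[1:]], dtype=float)
        preds.append(QaPrediction(
            target_id=target, model_id=name, local=local,
            global_score=None if np.isnan(glob) else glob))

    in_model = False
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        tok0 = line.split()[0].upper()
        if tok0 == "PFRMAT":
            saw_pfrmat = True
            if line.split()[1].upper() != "QA":
                raise ParseError(f"{path.name}:{ln}: PFRMAT is not QA")
        elif tok0 == "TARGET":
            target = line.split()[1]
        elif tok0 == "MODEL":
            if not saw_pfrmat:
                raise ParseError(f"{path.name}:{ln}: MODEL before PFRMAT QA")
            if target is None:
                raise ParseError(f"{path.name}:{ln}: MODEL before TARGET")
            flush()
            current_tokens = []
            in_model = True
        elif tok0 in ("END", "QMODE", "METHOD", "AUTHOR", "REMARK"):
            if tok0 == "END":
                flush()
                current_tokens = []
                in_model = False
        elif in_model:
            current_tokens.extend(line.split())
    flush()
    if not saw_pfrmat:
        raise ParseError(f"{path.name}:1: missing PFRMAT QA header")
    if target is None:
        raise ParseError(f"{path.name}:1: missing TARGET line")
    return preds


def write_casp_qa(preds: Sequence[QaPrediction], path,
                  values_per_line: int = 20, precision: int = 4) -> None:
    """Write predictions in CASP QA format; refuses negative local values."""
    if not preds:
        raise ValueError("no predictions to write")
    for p in preds:
        present = p.local[~np.isnan(p.local)]
        if np.any(present < 0):
            raise ValueError(f"{p.model_id}: negative local deviation")
    with open(path, "w") as fh:
        fh.write("PFRMAT QA\n")
        fh.write(f"TARGET {preds[0].target_id}\n")
        fh.write("QMODE 2\n")
        for i, p in enumerate(preds, start=1):
            fh.write(f"MODEL {i}\n")
            toks = [p.model_id]
            toks.append("X" if p.global_score is None
                        else f"{p.global_score:.{precision}f}")
            for v in p.local:
                toks.append("X" if np.isnan(v) else f"{v:.{precision}f}")
            for j in range(0, len(toks), values_per_line):
                fh.write(" ".join(toks[j:j + values_per_line]) + "\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# PSSM / DSSP / Rosetta / FASTA
# ---------------------------------------------------------------------------

def read_pssm(path, expected_length: Optional[int] = None) -> np.ndarray:
    """Read a PSI-BLAST ASCII PSSM into an (L, 20) log-odds matrix.

    Rows are recognised as lines starting with an integer position followed by
    a one-letter residue code and at least 20 numeric columns; the first 20
    numeric columns (the log-odds block) are kept.
    """
    path = Path(path)
    rows = []
    for raw in path.read_text().splitlines():
        parts = raw.split()
        if len(parts) < 22:
            continue
        if not parts[0].lstrip("-").isdigit():
            continue
        if len(parts[1]) != 1 or not parts[1].isalpha():
            continue
        try:
            vals = [float(x) for x in parts[2:22]]
        except ValueError:
            continue
        rows.append(vals)
    if not rows:
        raise ParseError(f"{path.name}: no PSSM rows found")
    mat = np.asarray(rows, dtype=float)
    if expected_length is not None and mat.shape[0] != expected_length:
        raise ParseError(
            f"{path.name}: PSSM has {mat.shape[0]} rows, expected "
            f"{expected_length}")
    return mat


def read_dssp_labels(path) -> tuple[str, np.ndarray]:
    """Read a DSSP output file into (3-state SS string, RSA array in [0,1]).

    The eight DSSP states are collapsed to three: H, G, I -> H; E, B -> E;
    everything else -> C.  Absolute accessibility is divided by the residue
    type's maximal accessible surface area and clamped to [0, 1].
    """
    from Bio.PDB.DSSP import make_dssp_dict

    path = Path(path)
    try:
        dssp_dict, keys = make_dssp_dict(str(path))
    except Exception as exc:  # Bio raises bare Exception subclasses here
        raise ParseError(f"{path.name}: not parseable as DSSP output: {exc}")
    ss_chars = []
    rsa = []
    for key in keys:
        aa, ss, acc = dssp_dict[key][:3]
        if ss in ("H", "G", "I"):
            ss3 = "H"
        elif ss in ("E", "B"):
            ss3 = "E"
        else:
            ss3 = "C"
        ss_chars.append(ss3)
        max_asa = MAX_ASA.get(aa.upper(), 200.0)
        rsa.append(min(1.0, max(0.0, float(acc) / max_asa)))
    if not ss_chars:
        raise ParseError(f"{path.name}: no residue lines in DSSP file")
    return "".join(ss_chars), np.asarray(rsa, dtype=float)


def read_rosetta_scores(path) -> np.ndarray:
    """Read a whitespace-delimited per-residue REF15 table into (L, 19).

    The file must have a header row; every data row must carry exactly 19
    numeric energy columns (a leading residue-index column is tolerated and
    dropped).
    """
    import pandas as pd

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:
        raise ParseError(f"{path.name}: unreadable Rosetta table: {exc}")
    if df.shape[0] == 0:
        raise ParseError(f"{path.name}: empty Rosetta table")
    num = df.select_dtypes(include=[np.number])
    if num.shape[1] == 20 and num.columns[0].lower() in ("res", "resi", "pos", "residue"):
        num = num.iloc[:, 1:]
    if num.shape[1] != 19:
        raise ParseError(
            f"{path.name}: expected 19 numeric energy columns, found "
            f"{num.shape[1]}")
    mat = num.to_numpy(dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ParseError(f"{path.name}: non-finite energy value")
    return mat


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA (or FASTA-like label) file into {name: string}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Superposition and GDT
# ---------------------------------------------------------------------------

def _kabsch_distances(model: ModelStructure, reference: ModelStructure):
    """Least-squares superpose shared Calphas; return per-shared-residue
    distances plus the shared index mask into the model."""
    shared, mi, ri = np.intersect1d(model.seq_index, reference.seq_index,
                                    return_indices=True)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} residues shared between model and reference; "
            "need >= 3 for superposition")
    P = model.coords[mi]       # moved set
    Q = reference.coords[ri]   # fixed set
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # Kabsch via SVD with proper-rotation correction
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    dists = np.linalg.norm((R @ Pc.T).T - Qc, axis=1)
    return dists, mi


def superpose_kabsch(model: ModelStructure,
                     reference: ModelStructure) -> DeviationProfile:
    """Per-residue deviations after one rigid-body Calpha superposition.

    Residues of the model absent from the reference receive NaN.  Requires at
    least three residues shared by author sequence number.
    """
    dists, mi = _kabsch_distances(model, reference)
    dev = np.full(len(model), np.nan)
    dev[mi] = dists
    return DeviationProfile(seq_index=model.seq_index.copy(),
                            deviations=dev, provenance="computed")


def gdt_ts_simple(model: ModelStructure, reference: ModelStructure) -> float:
    """Simplified GDT_TS in [0, 100] from a single Kabsch superposition.

    GDT_TS = 25 * (P1 + P2 + P4 + P8) where Pc is the fraction of shared
    Calphas within c Angstroms.  CASP's LGA instead maximises each Pc over
    many fragment superpositions, so these values are systematically equal or
    lower than official GDT_TS.
    """
    dists, _ = _kabsch_distances(model, reference)
    n = len(dists)
    total = sum((dists <= c).sum() / n for c in (1.0, 2.0, 4.0, 8.0))
    return float(25.0 * total)
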