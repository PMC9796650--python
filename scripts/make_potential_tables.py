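"""Estimate the statistical-potential reference tables.

Builds an ensemble of ideal-geometry synthetic structures, histograms the
geometric observables each potential scores (pseudo-bond angles by SS
state, burial by hydrophobicity class, pair distances by sequence
separation, contact class pairs, RSA by class, local packing), and writes
the Laplace-smoothed frequency tables to src/resqa/data/
potential_tables.json.  Deterministic; rerunning reproduces the file.
"""

import json
from pathlib import Path

import numpy as np

from resqa import synthdata
from resqa.features import _aa_class, pseudo_bond_angles

OUT = Path(__file__).resolve().parents[1] / "src" / "resqa" / "data" / \
    "potential_tables.json"

N_ANGLE_BINS = 12
BURIAL_EDGES = list(range(0, 34, 3)) + [100]
DIST_EDGES = [float(x) for x in np.arange(0.0, 18.0, 2.0)]
N_RSA_BINS = 5
VOL_EDGES = list(range(0, 13, 2)) + [100]


def main() -> None:
    angle = {s: np.ones(N_ANGLE_BINS) for s in "HEC"}
    burial = {c: np.ones(len(BURIAL_EDGES) - 1) for c in "hpc"}
    sepdist = {s: np.ones(len(DIST_EDGES) - 1)
               for s in ("short", "medium", "long")}
    contact = {p: 1.0 for p in ("cc", "ch", "cp", "hh", "hp", "pp")}
    rsa_tab = {c: np.ones(N_RSA_BINS) for c in "hpc"}
    vol = np.ones(len(VOL_EDGES) - 1)

    rng = np.random.default_rng(20240)
    for i in range(40):
        L = int(rng.integers(50, 120))
        spec = synthdata.SynthSpec(seed=1000 + i, length=L,
                                   target_id=f"REF{i:03d}")
        nat = synthdata.make_native(spec)
        ss = spec.ss_string
        coords = nat.coords
        dmat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)

        ang = pseudo_bond_angles(coords)
        for k, a in enumerate(ang):
            b = min(int(a / 180.0 * N_ANGLE_BINS), N_ANGLE_BINS - 1)
            angle[ss[k + 1]][b] += 1

        nb10 = (dmat < 10.0).sum(axis=1) - 1
        for j in range(L):
            b = np.clip(np.searchsorted(BURIAL_EDGES, nb10[j],
                                        side="right") - 1, 0,
                        len(BURIAL_EDGES) - 2)
            burial[_aa_class(nat.sequence[j])][b] += 1

        for name, lo, hi in (("short", 7, 12), ("medium", 12, 24),
                             ("long", 24, 10 ** 9)):
            ii, jj = np.triu_indices(L, k=lo)
            keep = (jj - ii) < hi
            d = dmat[ii[keep], jj[keep]]
            d = d[d < DIST_EDGES[-1]]
            if len(d):
                db = np.clip(np.searchsorted(DIST_EDGES, d,
                                             side="right") - 1, 0,
                             len(DIST_EDGES) - 2)
                np.add.at(sepdist[name], db, 1)

        ii, jj = np.where(np.triu(dmat < 8.0, k=3))
        for a, b in zip(ii, jj):
            key = "".join(sorted((_aa_class(nat.sequence[a]),
                                  _aa_class(nat.sequence[b]))))
            contact[key] += 1

        nb = (dmat < 10.0).sum(axis=1) - 1
        rsa = np.clip(1.0 - nb / max(nb.max(), 1), 0.0, 1.0)
        for j in range(L):
            b = min(int(rsa[j] * N_RSA_BINS), N_RSA_BINS - 1)
            rsa_tab[_aa_class(nat.sequence[j])][b] += 1

        nb65 = (dmat < 6.5).sum(axis=1) - 1
        for j in range(L):
            b = np.clip(np.searchsorted(VOL_EDGES, nb65[j],
                                        side="right") - 1, 0,
                        len(VOL_EDGES) - 2)
            vol[b] += 1

    def norm(d):
        return {k: list(v / v.sum()) for k, v in d.items()}

    total_contacts = sum(contact.values())
    tables = {
        "angle": {"bins": N_ANGLE_BINS, "cond": norm(angle),
                  "ref": list(sum(angle.values()) /
                              sum(angle.values()).sum())},
        "burial": {"edges": BURIAL_EDGES, "cond": norm(burial)},
        "sepdist": {"dist_edges": DIST_EDGES, "cond": norm(sepdist)},
        "contact": {"pair": {k: v / total_contacts
                             for k, v in contact.items()}},
        "rsa": {"bins": N_RSA_BINS, "cond": norm(rsa_tab)},
        "volume": {"edges": VOL_EDGES, "probs": list(vol / vol.sum())},
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        json.dump(tables, fh, indent=1)
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
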