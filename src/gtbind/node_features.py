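"""Per-residue node features.

The node feature matrix H concatenates a language-model embedding block
(min-max normalized to [0, 1] with statistics learned on training data)
and a 14-dimensional structural group in the DSSP tradition:
1 relative solvent accessibility + 9 secondary-structure one-hot columns
(8 DSSP states H,B,E,G,I,T,S,- plus an explicit "unassigned") + 4 backbone
torsion terms (sin/cos of phi and psi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from Bio.PDB.DSSP import make_dssp_dict

DSSP_STATES = "HBEGITS-"          # the 8 classic DSSP codes
SS_COLUMNS = list(DSSP_STATES) + ["unassigned"]
DSSP_DIM = 1 + len(SS_COLUMNS) + 4  # RSA + SS one-hot + torsion sin/cos = 14

# Theoretical maximum accessible surface areas (A^2) per amino acid,
# Tien et al. 2013.  'X' falls back to glycine with a warning.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class NodeFeatureMatrix:
    """The assembled per-residue feature matrix with block provenance."""

    H: np.ndarray                  # (n, d)
    block_spans: dict              # {"embedding": (0, d_emb), "dssp": (d_emb, d)}
    norm_stats: tuple | None = None  # (x_min, x_max) per embedding column

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def d(self) -> int:
        return self.H.shape[1]


# ---------------------------------------------------------------------------
# embedding normalization

def fit_minmax_stats(matrices) -> tuple[np.ndarray, np.ndarray]:
    """Per-column min/max over a list of (n_i, d_emb) training matrices."""
    stacked = np.vstack([np.asarray(m, dtype=float) for m in matrices])
    return stacked.min(axis=0), stacked.max(axis=0)


def minmax_normalize(M, stats) -> np.ndarray:
    """Map each column to (x - x_min)/(x_max - x_min), clipped to [0, 1].

    Columns that were constant on the training set map to 0.
    """
    M = np.asarray(M, dtype=float)
    x_min, x_max = (np.asarray(s, dtype=float) for s in stats)
    if M.shape[1] != x_min.shape[0] or M.shape[1] != x_max.shape[0]:
        raise ValueError(
            f"column mismatch: matrix has {M.shape[1]}, stats have "
            f"{x_min.shape[0]}/{x_max.shape[0]}"
        )
    span = x_max - x_min
    if np.any(span < 0):
        raise ValueError("x_max < x_min in normalization stats")
    safe = np.where(span > 0, span, 1.0)
    out = (M - x_min) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# torsions

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians) of four points, IUPAC sign convention.

    Returns ``nan`` for degenerate (collinear) quadruples.
    """
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    if (np.linalg.norm(np.cross(b0, b1)) < 1e-8
            or np.linalg.norm(np.cross(b1, b2)) < 1e-8):
        return float("nan")
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.arctan2(y, x))


def backbone_torsions(backbone) -> np.ndarray:
    """(sin phi, cos phi, sin psi, cos psi) per residue from an (n, 4, 3) backbone.

    phi_i uses (C_{i-1}, N_i, CA_i, C_i); psi_i uses (N_i, CA_i, C_i, N_{i+1}).
    Undefined angles (termini, degenerate geometry) encode as (0, 0).
    """
    bb = np.asarray(backbone, dtype=float)
    n = bb.shape[0]
    if bb.shape != (n, 4, 3):
        raise ValueError("backbone must be (n, 4, 3) with atoms N, CA, C, O")
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]
    out = np.zeros((n, 4))
    for i in range(n):
        if i > 0:
            phi = dihedral(C[i - 1], N[i], CA[i], C[i])
            if np.isnan(phi):
                warnings.warn(f"degenerate phi at residue {i}; encoding (0, 0)")
            else:
                out[i, 0], out[i, 1] = np.sin(phi), np.cos(phi)
        if i < n - 1:
            psi = dihedral(N[i], CA[i], C[i], N[i + 1])
            if np.isnan(psi):
                warnings.warn(f"degenerate psi at residue {i}; encoding (0, 0)")
            else:
                out[i, 2], out[i, 3] = np.sin(psi), np.cos(psi)
    return out


# ---------------------------------------------------------------------------
# solvent accessibility

def _atom_array(coords, elements, res_ids):
    arr = struc.AtomArray(len(coords))
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.element = np.asarray(elements)
    arr.atom_name = np.asarray(elements)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.array(["GLY"] * len(coords))
    arr.chain_id = np.array(["A"] * len(coords))
    return arr


def relative_solvent_accessibility(
    record, probe_radius: float = 1.4, sphere_points: int = 100,
    max_asa_table: dict | None = None,
) -> np.ndarray:
    """Per-residue RSA in [0, 1] by Shrake-Rupley sphere sampling.

    Uses the full N/CA/C/O backbone when present, else Calpha pseudo-atoms
    (a documented approximation for side-chain-free synthetic traces).
    ASA is divided by a fixed per-amino-acid maximum (Tien et al. theoretical
    values); unknown residue types use the glycine maximum with a warning.
    """
    table = max_asa_table or MAX_ASA
    n = record.n_residues
    if record.backbone is not None:
        coords = record.backbone.reshape(-1, 3)
        elements = np.tile(np.array(["N", "C", "C", "O"]), n)
        res_ids = np.repeat(np.arange(n), 4)
    else:
        coords = record.ca_coords
        elements = np.array(["C"] * n)
        res_ids = np.arange(n)
    arr = _atom_array(coords, elements, res_ids)
    asa_atom = struc.sasa(
        arr, probe_radius=probe_radius, point_number=sphere_points,
        vdw_radii="Single",
    )
    asa = np.zeros(n)
    np.add.at(asa, res_ids, np.nan_to_num(asa_atom))
    rsa = np.empty(n)
    for i, aa in enumerate(record.sequence):
        if aa not in table:
            warnings.warn(f"unknown residue {aa!r}; using glycine max ASA")
        rsa[i] = asa[i] / table.get(aa, table["G"])
    return np.clip(rsa, 0.0, 1.0)


# ---------------------------------------------------------------------------
# secondary structure

def read_dssp_file(path) -> tuple[str, np.ndarray, np.ndarray]:
    """Parse a classic DSSP output file: (ss_string, acc, phi_psi_degrees)."""
    dssp_dict, keys = make_dssp_dict(str(path))
    ss, acc, angles = [], [], []
    for key in keys:
        aa, s, a, phi, psi = dssp_dict[key][:5]
        ss.append(s if s in DSSP_STATES else "-")
        acc.append(a)
        angles.append((phi, psi))
    return "".join(ss), np.array(acc, dtype=float), np.array(angles, dtype=float)


def ss_onehot_from_string(ss: str) -> np.ndarray:
    """One-hot encode a string of DSSP codes into n x 9 (8 states + unassigned)."""
    out = np.zeros((len(ss), len(SS_COLUMNS)))
    for i, s in enumerate(ss):
        j = DSSP_STATES.index(s) if s in DSSP_STATES else len(SS_COLUMNS) - 1
        out[i, j] = 1.0
    return out


def coarse_ss_from_torsions(torsions: np.ndarray) -> str:
    """Approximate 3-state assignment (H / E / -) from phi/psi.

    A deliberately simple Ramachandran-region rule for the internal,
    DSSP-free fallback: the alpha region (phi in [-160, -20], psi in
    [-120, 50]) maps to 'H', the beta region (phi in [-180, -20], psi in
    [90, 180] or [-180, -150]) to 'E', everything else (including residues
    with undefined torsions) to '-'.
    """
    t = np.asarray(torsions, dtype=float)
    ss = []
    for i in range(t.shape[0]):
        sphi, cphi, spsi, cpsi = t[i]
        if (sphi, cphi) == (0.0, 0.0) or (spsi, cpsi) == (0.0, 0.0):
            ss.append("-")
            continue
        phi = np.degrees(np.arctan2(sphi, cphi))
        psi = np.degrees(np.arctan2(spsi, cpsi))
        if -160 <= phi <= -20 and -120 <= psi <= 50:
            ss.append("H")
        elif -180 <= phi <= -20 and (psi >= 90 or psi <= -150):
            ss.append("E")
        else:
            ss.append("-")
    return "".join(ss)


def secondary_structure_onehot(n: int, dssp_path=None, torsions=None) -> np.ndarray:
    """n x 9 secondary-structure one-hot from a DSSP file or the torsion fallback.

    With neither source, every residue is "unassigned".
    """
    if dssp_path is not None:
        ss, _, _ = read_dssp_file(dssp_path)
        if len(ss) != n:
            raise ValueError(f"DSSP file has {len(ss)} residues, expected {n}")
        return ss_onehot_from_string(ss)
    if torsions is not None:
        return ss_onehot_from_string(coarse_ss_from_torsions(torsions))
    out = np.zeros((n, len(SS_COLUMNS)))
    out[:, -1] = 1.0
    return out


# ---------------------------------------------------------------------------
# assembly

def dssp_feature_group(record, dssp_path=None, sphere_points: int = 100) -> np.ndarray:
    """The 14-dim structural group: [RSA | SS one-hot (9) | torsion sin/cos (4)].

    DSSP output files take priority for SS, accessibility, and torsions;
    otherwise the internal fallback computes RSA by sphere sampling and,
    when a full backbone is present, torsions and a coarse SS assignment.
    """
    n = record.n_residues
    if dssp_path is not None:
        ss, acc, angles = read_dssp_file(dssp_path)
        if len(ss) != n:
            raise ValueError(f"DSSP file has {len(ss)} residues, expected {n}")
        rsa = np.array([
            min(1.0, acc[i] / MAX_ASA.get(record.sequence[i], MAX_ASA["G"]))
            for i in range(n)
        ])
        onehot = ss_onehot_from_string(ss)
        rad = np.radians(angles)
        tors = np.zeros((n, 4))
        # DSSP marks undefined angles as 360.0
        phi_ok = np.abs(angles[:, 0]) <= 180.0
        psi_ok = np.abs(angles[:, 1]) <= 180.0
        tors[phi_ok, 0] = np.sin(rad[phi_ok, 0])
        tors[phi_ok, 1] = np.cos(rad[phi_ok, 0])
        tors[psi_ok, 2] = np.sin(rad[psi_ok, 1])
        tors[psi_ok, 3] = np.cos(rad[psi_ok, 1])
    else:
        rsa = relative_solvent_accessibility(record, sphere_points=sphere_points)
        if record.backbone is not None:
            tors = backbone_torsions(record.backbone)
            onehot = secondary_structure_onehot(n, torsions=tors)
        else:
            tors = np.zeros((n, 4))
            onehot = secondary_structure_onehot(n)
    return np.hstack([rsa[:, None], onehot, tors])


def assemble_node_features(embeddings: np.ndarray, dssp_group: np.ndarray,
                           norm_stats=None) -> NodeFeatureMatrix:
    """Concatenate [normalized embeddings | 14-dim structural group]."""
    embeddings = np.asarray(embeddings, dtype=float)
    dssp_group = np.asarray(dssp_group, dtype=float)
    if embeddings.shape[0] != dssp_group.shape[0]:
        raise ValueError(
            f"row mismatch: {embeddings.shape[0]} embedding rows vs "
            f"{dssp_group.shape[0]} structural rows"
        )
    if dssp_group.shape[1] != DSSP_DIM:
        raise ValueError(f"structural group must have {DSSP_DIM} columns")
    d_emb = embeddings.shape[1]
    H = np.hstack([embeddings, dssp_group])
    return NodeFeatureMatrix(
        H=H,
        block_spans={"embedding": (0, d_emb), "dssp": (d_emb, d_emb + DSSP_DIM)},
        norm_stats=norm_stats,
    )
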