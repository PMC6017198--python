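"""Synthetic inputs for exercising the full pipeline without external data:
ideal-geometry toy structures, wild-type/mutant rigid-cluster histogram
pairs, and labeled feature tables with a planted linear feature-to-ddG
relationship plus Gaussian noise.

The histogram generator emulates the one-giant-cluster regime of folded
proteins (one dominant largest rigid cluster over a truncated power-law sea
of small clusters); the mutant shrinks the giant cluster and redistributes
the atoms to small clusters, with a controllable perturbation strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import rd_score
from .features import (BIN_LABELS, CATEGORY_ORDER, FEATURE_NAMES, SS_ORDER,
                       MutationRecord, cluster_fractions)
from .rigidity import ClusterHistogram
from .structure import AtomRecord, MutationSpec, Structure

_DEFAULT_PLANTED = {
    "mut1_sasa_rel": -0.03,
    "temperature": 0.02,
    "ph": -0.10,
    "rd": 0.004,
    "is_double": 0.5,
}


@dataclass
class SyntheticSpec:
    n_records: int = 300
    n_groups: int = 60
    n_atoms: int = 1500
    lrc_fraction: float = 0.4        # LRC size as a fraction of all atoms
    powerlaw_exponent: float = 2.5   # small-cluster size distribution
    perturbation: float = 0.3        # mutation strength in [0, 1]
    planted_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PLANTED))
    noise_sd: float = 0.5            # kcal/mol
    double_fraction: float = 0.25
    rd_scheme: str = "sm2"
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 3:
            raise ValueError("need at least 3 groups")
        if self.n_records < self.n_groups:
            raise ValueError("n_records must be >= n_groups")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.perturbation <= 1:
            raise ValueError("perturbation must be in [0, 1]")


# ---------------------------------------------------------------------------
# Toy structures (ideal backbone geometry via chained internal coordinates)
# ---------------------------------------------------------------------------

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
         "CA-CB": 1.530}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7,
          "CA-C-O": 120.8, "N-CA-CB": 110.5}
_TORSIONS = {"polyala_helix": (-57.0, -47.0),
             "extended_strand": (-139.0, 135.0)}


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place a new point D given three reference points and internal
    coordinates (bond |DC|, angle D-C-B, torsion D-C-B-A)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_toy_structure(kind: str = "polyala_helix", n_res: int = 10,
                      chain: str = "A", structure_id: str | None = None) -> Structure:
    """Ideal-geometry polyalanine backbone (N, CA, C, O, CB per residue).

    `kind` fixes the backbone dihedrals: polyala_helix uses phi/psi =
    -57/-47 degrees, extended_strand -139/135.
    """
    if n_res < 3:
        raise ValueError("need at least 3 residues")
    if kind not in _TORSIONS:
        raise ValueError(f"unknown toy-structure kind {kind!r}")
    phi, psi = _TORSIONS[kind]
    omega = 180.0

    # Seed the first residue's N, CA, C in a plane.
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(180.0 - _ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([math.cos(ang), math.sin(ang), 0.0])
    backbone = [[n0, ca0, c0]]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_new = _place(n_prev, ca_prev, c_prev, _BOND["C-N"],
                       _ANGLE["CA-C-N"], psi)
        ca_new = _place(ca_prev, c_prev, n_new, _BOND["N-CA"],
                        _ANGLE["C-N-CA"], omega)
        c_new = _place(c_prev, n_new, ca_new, _BOND["CA-C"],
                       _ANGLE["N-CA-C"], phi)
        backbone.append([n_new, ca_new, c_new])

    atoms: list[AtomRecord] = []
    serial = 1

    def add(name, element, resseq, coords):
        nonlocal serial
        atoms.append(AtomRecord(serial=serial, atom_name=name, element=element,
                                residue_name="ALA", chain_id=chain,
                                residue_seq=resseq, coords=coords))
        serial += 1

    for i, (n_at, ca_at, c_at) in enumerate(backbone):
        resseq = i + 1
        add("N", "N", resseq, n_at)
        add("CA", "C", resseq, ca_at)
        add("C", "C", resseq, c_at)
        # carbonyl O: torsion N-CA-C-O = psi + 180 (trans to the next N)
        o_at = _place(n_at, ca_at, c_at, _BOND["C-O"], _ANGLE["CA-C-O"],
                      psi + 180.0)
        add("O", "O", resseq, o_at)
        # CB: tetrahedral branch off CA
        cb = _place(o_at, c_at, ca_at, _BOND["CA-CB"], _ANGLE["N-CA-CB"],
                    phi + 120.0)
        add("CB", "C", resseq, cb)
    return Structure(atoms=atoms,
                     id=structure_id or f"{kind}_{n_res}")


# ---------------------------------------------------------------------------
# Cluster-histogram pairs
# ---------------------------------------------------------------------------

def _powerlaw_sizes(rng, total: int, cap: int, exponent: float) -> list[int]:
    sizes = np.arange(1, cap + 1)
    prob = sizes ** (-exponent)
    prob = prob / prob.sum()
    out: list[int] = []
    remaining = total
    while remaining > 0:
        s = int(rng.choice(sizes, p=prob))
        if s > remaining:
            s = remaining
        out.append(s)
        remaining -= s
    return out


def gen_histogram_pair(spec: SyntheticSpec, seed: int | None = None
                       ) -> tuple[ClusterHistogram, ClusterHistogram]:
    """A wild-type histogram plus a perturbed mutant conserving atom count.

    The wild type holds one giant cluster (lrc_fraction of atoms) over a
    truncated power law of small clusters; the mutant moves
    perturbation * lrc/2 atoms out of the giant cluster into small ones, so
    LRC_mut <= LRC_wt always.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lrc = int(round(spec.lrc_fraction * spec.n_atoms))
    cap = min(50, lrc - 1)
    if cap < 1:
        raise ValueError("atom count too small for the requested LRC")
    small = _powerlaw_sizes(rng, spec.n_atoms - lrc, cap, spec.powerlaw_exponent)
    wt = ClusterHistogram.from_sizes(small + [lrc])

    moved = int(math.floor(spec.perturbation * lrc / 2))
    lrc_mut = lrc - moved
    if lrc_mut <= cap:
        raise ValueError("atom count too small for the requested LRC "
                         "under this perturbation")
    if moved == 0:
        mut = ClusterHistogram(counts=dict(wt.counts),
                               total_atoms=wt.total_atoms)
        return wt, mut
    redistributed = _powerlaw_sizes(rng, moved, min(10, cap),
                                    spec.powerlaw_exponent)
    mut = ClusterHistogram.from_sizes(small + redistributed + [lrc_mut])
    return wt, mut


# ---------------------------------------------------------------------------
# Labeled feature tables with a planted signal
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_onehot(rng, prefix: str, labels) -> dict[str, float]:
    pick = labels[int(rng.integers(len(labels)))]
    return {f"{prefix}_{lab}": float(lab == pick) for lab in labels}


def _group_structural_features(rng, spec: SyntheticSpec) -> dict[str, float]:
    values: dict[str, float] = dict.fromkeys(FEATURE_NAMES, 0.0)
    is_double = rng.random() < spec.double_fraction
    sites = ("mut1", "mut2") if is_double else ("mut1",)
    for site in sites:
        values[f"{site}_sasa_rel"] = float(rng.uniform(0, 100))
        values[f"{site}_sasa_abs"] = values[f"{site}_sasa_rel"] * 2.4
        values.update(_random_onehot(rng, f"{site}_ss", SS_ORDER))
        values.update(_random_onehot(rng, f"{site}_wt", CATEGORY_ORDER))
        values.update(_random_onehot(rng, f"{site}_target", CATEGORY_ORDER))
    pert = float(rng.uniform(0, spec.perturbation))
    sub = SyntheticSpec(**{**spec.__dict__, "perturbation": pert,
                           "planted_weights": dict(spec.planted_weights)})
    wt_hist, mut_hist = gen_histogram_pair(sub, seed=int(rng.integers(2 ** 31)))
    values["rd"] = rd_score(wt_hist, mut_hist, spec.rd_scheme).value
    for label, frac in zip(BIN_LABELS, cluster_fractions(wt_hist)):
        values[f"wt_frac_{label}"] = frac
    for label, frac in zip(BIN_LABELS, cluster_fractions(mut_hist)):
        values[f"mut_frac_{label}"] = frac
    values["is_double"] = float(is_double)
    return values


def gen_feature_dataset(spec: SyntheticSpec
                        ) -> tuple[list[MutationRecord], pd.DataFrame, pd.Series]:
    """(records, feature table, ddG labels) with ddG a planted linear
    function of named features plus Gaussian noise.

    Records within a group share one mutation combination (hence all
    structural features); temperature and pH vary per record, so replicate
    groups exercise the grouped split.
    """
    for name in spec.planted_weights:
        if name not in FEATURE_NAMES:
            raise KeyError(f"planted weight names unknown feature {name!r}")
    rng = np.random.default_rng(spec.seed)
    # every group gets one record, the rest are replicates
    extra = rng.integers(0, spec.n_groups, size=spec.n_records - spec.n_groups)
    group_sizes = np.bincount(extra, minlength=spec.n_groups) + 1

    rows, records = [], []
    for g in range(spec.n_groups):
        base = _group_structural_features(rng, spec)
        is_double = base["is_double"] > 0
        muts = [MutationSpec("A", int(rng.integers(1, 200)),
                             _AA[int(rng.integers(20))], "G")]
        if is_double:
            muts.append(MutationSpec("A", muts[0].position + 1 +
                                     int(rng.integers(1, 50)),
                                     _AA[int(rng.integers(20))], "G"))
        for _ in range(group_sizes[g]):
            row = dict(base)
            row["temperature"] = float(rng.uniform(4, 80))
            row["ph"] = float(rng.uniform(2, 11))
            rows.append(row)
            records.append((f"P{g:03d}", tuple(muts), row))
    X = pd.DataFrame(rows, columns=FEATURE_NAMES, dtype=float)
    signal = np.zeros(len(X))
    for name, w in spec.planted_weights.items():
        signal += w * X[name].to_numpy()
    y = pd.Series(signal + rng.normal(0.0, spec.noise_sd, size=len(X)),
                  name="ddg")
    out_records = [
        MutationRecord(structure_id=sid, mutations=muts, ddg=float(y[i]),
                       temperature=row["temperature"], ph=row["ph"])
        for i, (sid, muts, row) in enumerate(records)
    ]
    return out_records, X, y
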