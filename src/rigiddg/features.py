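"""Feature-vector assembly for single/double mutants and the grouped
train/dev/test split.

The fixed-order feature block (80 entries) holds, per mutation site, SASA
(absolute A^2 + relative %), a secondary-structure one-hot, and one-hot
residue categories for the wild-type and target residues; globally it holds
the experimental temperature and pH, the Rigidity Distance score, 24
rigid-cluster-fraction bins for each of the wild type and mutant, and a
single/double flag.  For single mutants every second-site (mut2) entry is
exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import WeightScheme, get_scheme, rd_score
from .rigidity import (ClusterHistogram, RigidityParams,
                       build_constraint_graph, pebble_game_decompose)
from .structure import (MutationSpec, Structure, assign_secondary_structure,
                        compute_sasa)

logger = logging.getLogger(__name__)

RESIDUE_CATEGORIES = {
    "charged": frozenset("DEKR"),
    "polar": frozenset("NQST"),
    "aromatic": frozenset("FHWY"),
    "hydrophobic": frozenset("ACGILMPV"),
}
CATEGORY_ORDER = ("charged", "polar", "aromatic", "hydrophobic")
SS_ORDER = ("helix", "sheet", "turn", "coil")

#: cluster-fraction bins: sizes 2..20 individually, then 21-30, 31-50,
#: 51-100, 101-1000, 1001+ (size-1 clusters contribute to no bin)
CLUSTER_BINS: list[tuple[int, float]] = (
    [(s, s) for s in range(2, 21)]
    + [(21, 30), (31, 50), (51, 100), (101, 1000), (1001, np.inf)]
)
BIN_LABELS = [f"{lo}" if lo == hi else
              (f"{lo}_plus" if np.isinf(hi) else f"{lo}_{int(hi)}")
              for lo, hi in CLUSTER_BINS]


def residue_category(code: str) -> str:
    """Map a 1-letter amino-acid code to its category."""
    for name, members in RESIDUE_CATEGORIES.items():
        if code in members:
            return name
    raise KeyError(f"unknown amino-acid code {code!r}")


def cluster_fractions(h: ClusterHistogram) -> np.ndarray:
    """Fraction of all atoms lying in rigid clusters of each size bin."""
    if h.total_atoms <= 0:
        raise ValueError("histogram has zero total atoms")
    out = np.zeros(len(CLUSTER_BINS))
    for size, count in h.counts.items():
        for b, (lo, hi) in enumerate(CLUSTER_BINS):
            if lo <= size <= hi:
                out[b] += size * count
                break
    return out / h.total_atoms


def _site_feature_names(prefix: str) -> list[str]:
    names = [f"{prefix}_sasa_abs", f"{prefix}_sasa_rel"]
    names += [f"{prefix}_ss_{s}" for s in SS_ORDER]
    names += [f"{prefix}_wt_{c}" for c in CATEGORY_ORDER]
    names += [f"{prefix}_target_{c}" for c in CATEGORY_ORDER]
    return names


def feature_names() -> list[str]:
    """The fixed, documented feature order (length 80)."""
    names = _site_feature_names("mut1") + _site_feature_names("mut2")
    names += ["temperature", "ph", "rd"]
    names += [f"wt_frac_{b}" for b in BIN_LABELS]
    names += [f"mut_frac_{b}" for b in BIN_LABELS]
    names += ["is_double"]
    return names


FEATURE_NAMES = feature_names()
N_FEATURES = len(FEATURE_NAMES)


@dataclass
class MutationRecord:
    structure_id: str
    mutations: tuple[MutationSpec, ...]
    ddg: float
    temperature: float
    ph: float

    def __post_init__(self):
        self.mutations = tuple(self.mutations)
        if not 1 <= len(self.mutations) <= 2:
            raise ValueError("a record carries one or two mutations")
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")

    @property
    def is_double(self) -> bool:
        return len(self.mutations) == 2

    @property
    def group_key(self) -> str:
        """Unique wild-type + mutation-combination identity."""
        muts = sorted(str(m) for m in self.mutations)
        return self.structure_id + "|" + "|".join(muts)


def _site_features(rec_mut: MutationSpec, wt: Structure) -> dict[str, float]:
    prefix_vals: dict[str, float] = {}
    absolute, relative = compute_sasa(wt, (rec_mut.chain, rec_mut.position))
    prefix_vals["sasa_abs"] = absolute
    prefix_vals["sasa_rel"] = relative
    ss = assign_secondary_structure(wt, (rec_mut.chain, rec_mut.position))
    for s in SS_ORDER:
        prefix_vals[f"ss_{s}"] = float(s == ss)
    wt_cat = residue_category(rec_mut.wt_code)
    tg_cat = residue_category(rec_mut.target_code)
    for c in CATEGORY_ORDER:
        prefix_vals[f"wt_{c}"] = float(c == wt_cat)
        prefix_vals[f"target_{c}"] = float(c == tg_cat)
    return prefix_vals


def assemble_features(rec: MutationRecord, wt: Structure, mut: Structure,
                      scheme: str | WeightScheme = "sm1",
                      rigidity_params: RigidityParams | None = None,
                      wt_hist: ClusterHistogram | None = None,
                      mut_hist: ClusterHistogram | None = None) -> pd.Series:
    """Assemble the fixed-order feature vector for one mutation record.

    SASA and secondary structure are computed on the wild-type structure
    (the truncated mutant side chain would distort them); cluster histograms
    are decomposed on demand unless supplied.
    """
    scheme = get_scheme(scheme)
    if wt_hist is None:
        wt_hist = ClusterHistogram.from_decomposition(
            pebble_game_decompose(build_constraint_graph(wt, rigidity_params)))
    if mut_hist is None:
        mut_hist = ClusterHistogram.from_decomposition(
            pebble_game_decompose(build_constraint_graph(mut, rigidity_params)))
    values = dict.fromkeys(FEATURE_NAMES, 0.0)
    for i, m in enumerate(rec.mutations, start=1):
        for k, v in _site_features(m, wt).items():
            values[f"mut{i}_{k}"] = v
    values["temperature"] = rec.temperature
    values["ph"] = rec.ph
    values["rd"] = rd_score(wt_hist, mut_hist, scheme).value
    for label, frac in zip(BIN_LABELS, cluster_fractions(wt_hist)):
        values[f"wt_frac_{label}"] = frac
    for label, frac in zip(BIN_LABELS, cluster_fractions(mut_hist)):
        values[f"mut_frac_{label}"] = frac
    values["is_double"] = float(rec.is_double)
    return pd.Series(values, index=FEATURE_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# Grouped train/dev/test split
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    train: list[int]
    dev: list[int]
    test: list[int]
    group_keys: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = ([(i, "train") for i in self.train]
                + [(i, "dev") for i in self.dev]
                + [(i, "test") for i in self.test])
        return (pd.DataFrame(rows, columns=["index", "set"])
                .sort_values("index").reset_index(drop=True))


def grouped_split(records, fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0, key=None) -> DatasetSplit:
    """Split records into train/dev/test keeping every group whole.

    `records` is a sequence of MutationRecord (grouped by their wild type +
    mutation combination) or arbitrary objects with `key` supplying the group
    label.  Shuffled groups are assigned greedily to whichever set has the
    largest remaining record deficit.
    """
    fractions = tuple(fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions) \
            or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three positives summing to 1")
    if key is None:
        key = lambda r: r.group_key  # noqa: E731
    keys = [key(r) for r in records]
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    if len(groups) < 3:
        raise ValueError(f"need at least 3 groups, got {len(groups)}")
    order = list(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    n = len(keys)
    targets = [f * n for f in fractions]
    counts = [0, 0, 0]
    sets: tuple[list[int], list[int], list[int]] = ([], [], [])
    for g in order:
        deficits = [t - c for t, c in zip(targets, counts)]
        dest = int(np.argmax(deficits))
        sets[dest].extend(groups[g])
        counts[dest] += len(groups[g])
    return DatasetSplit(train=sorted(sets[0]), dev=sorted(sets[1]),
                        test=sorted(sets[2]), group_keys=keys)


# ---------------------------------------------------------------------------
# Record-table I/O
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["structure_id", "chain", "pos", "wt", "target",
                  "chain2", "pos2", "wt2", "target2", "ddg",
                  "temperature", "ph"]


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        m1 = r.mutations[0]
        row = {"structure_id": r.structure_id, "chain": m1.chain,
               "pos": m1.position, "wt": m1.wt_code, "target": m1.target_code,
               "chain2": "", "pos2": "", "wt2": "", "target2": "",
               "ddg": r.ddg, "temperature": r.temperature, "ph": r.ph}
        if r.is_double:
            m2 = r.mutations[1]
            row.update(chain2=m2.chain, pos2=m2.position,
                       wt2=m2.wt_code, target2=m2.target_code)
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[MutationRecord]:
    records = []
    for _, row in df.iterrows():
        muts = [MutationSpec(str(row["chain"]), int(row["pos"]),
                             str(row["wt"]), str(row["target"]))]
        if str(row.get("chain2", "") or "") and str(row.get("pos2", "") or ""):
            muts.append(MutationSpec(str(row["chain2"]), int(float(row["pos2"])),
                                     str(row["wt2"]), str(row["target2"])))
        records.append(MutationRecord(
            structure_id=str(row["structure_id"]), mutations=tuple(muts),
            ddg=float(row["ddg"]), temperature=float(row["temperature"]),
            ph=float(row["ph"])))
    return records


def read_records(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return frame_to_records(df)


def write_records(records, path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
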