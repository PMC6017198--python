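"""Rigidity Distance (RD): a signed, weighted comparison of the wild-type
and mutant rigid-cluster size distributions.

RD = sum_i  i * w(i) * (WT_i - Mut_i)

where WT_i / Mut_i count clusters of size i (atoms).  Three weightings are
provided: dm (uniform, w = 1), lm (linear ramp between the wild type's
smallest and largest cluster sizes), and sm (sigmoid in cluster size, with
named presets sm1..sm5).  A positive score means the mutant lost rigid
structure relative to the wild type under the chosen weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.special import expit

from .rigidity import ClusterHistogram

logger = logging.getLogger(__name__)

#: sigmoid weights below this are truncated to exactly 0
SIGMOID_TRUNCATION = 1e-3


def linear_weight(i: int, s_min: int, s_max: int) -> float:
    """Normalized linear ramp: 0 at s_min, 1 at s_max (1 if degenerate)."""
    if s_max == s_min:
        return 1.0
    if i < s_min or i > s_max:
        logger.warning("cluster size %d outside [%d, %d]; weight clipped",
                       i, s_min, s_max)
        i = min(max(i, s_min), s_max)
    return (i - s_min) / (s_max - s_min)


def sigmoid_weight(i: float, k: float, x0: float,
                   truncation: float = SIGMOID_TRUNCATION) -> float:
    """Logistic weight 1/(1 + exp(-k (i - x0))), small values truncated to 0."""
    if k <= 0:
        raise ValueError("sigmoid slope k must be > 0")
    w = float(expit(k * (i - x0)))
    return 0.0 if w < truncation else w


@dataclass(frozen=True)
class WeightScheme:
    """A named RD weighting.

    kind 'dm' ignores all parameters; 'sm' uses (k, x0); 'lm' uses
    (s_min, s_max), which are normally derived from the wild-type histogram
    at scoring time but may be pinned via :meth:`lm_from_histogram`.
    """
    name: str
    kind: str  # dm | lm | sm
    k: float = 1.0
    x0: float = 0.0
    s_min: int | None = None
    s_max: int | None = None

    def __post_init__(self):
        if self.kind not in ("dm", "lm", "sm"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "sm" and self.k <= 0:
            raise ValueError("sigmoid slope must be > 0")
        if (self.s_min is not None and self.s_max is not None
                and self.s_max < self.s_min):
            raise ValueError("s_max must be >= s_min")

    @classmethod
    def lm_from_histogram(cls, wt: ClusterHistogram, name: str = "lm") -> "WeightScheme":
        return cls(name=name, kind="lm", s_min=wt.smallest, s_max=wt.lrc)

    @property
    def run(self) -> int:
        """Denominator of the lm ramp's slope, s_max - s_min."""
        if self.kind != "lm" or self.s_min is None or self.s_max is None:
            raise ValueError("run is defined for a bound lm scheme only")
        return self.s_max - self.s_min

    def weight(self, i: int, wt: ClusterHistogram | None = None) -> float:
        if self.kind == "dm":
            return 1.0
        if self.kind == "lm":
            s_min, s_max = self.s_min, self.s_max
            if s_min is None or s_max is None:
                if wt is None:
                    raise ValueError("unbound lm scheme needs a wild-type histogram")
                s_min, s_max = wt.smallest, wt.lrc
            return linear_weight(i, s_min, s_max)
        return sigmoid_weight(i, self.k, self.x0)


#: Named presets.  sm1 realizes the near-step weighting in which clusters of
#: 10 or fewer atoms receive weight 0; sm2 is the documented (0.025, 300)
#: sigmoid.  sm3-sm5 have no published parameters; the defaults below are
#: package placeholders and are expected to be overridden from config.
SCHEME_BANK: dict[str, WeightScheme] = {
    "dm": WeightScheme("dm", "dm"),
    "lm": WeightScheme("lm", "lm"),
    "sm1": WeightScheme("sm1", "sm", k=20.0, x0=10.5),
    "sm2": WeightScheme("sm2", "sm", k=0.025, x0=300.0),
    "sm3": WeightScheme("sm3", "sm", k=0.05, x0=50.0),
    "sm4": WeightScheme("sm4", "sm", k=0.05, x0=100.0),
    "sm5": WeightScheme("sm5", "sm", k=0.05, x0=200.0),
}


def get_scheme(name: str | WeightScheme) -> WeightScheme:
    if isinstance(name, WeightScheme):
        return name
    try:
        return SCHEME_BANK[name]
    except KeyError:
        raise KeyError(f"unknown RD scheme {name!r}; known: "
                       f"{sorted(SCHEME_BANK)}") from None


@dataclass(frozen=True)
class RDScore:
    value: float
    scheme: str


def rd_score(wt: ClusterHistogram, mut: ClusterHistogram,
             scheme: str | WeightScheme = "sm1") -> RDScore:
    """Rigidity Distance between wild-type and mutant cluster histograms.

    The sum runs over cluster sizes up to the wild-type LRC, extended to the
    mutant LRC when the mutant grew a larger cluster (logged).
    """
    if not wt.counts or not mut.counts:
        raise ValueError("empty cluster histogram")
    scheme = get_scheme(scheme)
    bound = wt.lrc
    if mut.lrc > bound:
        logger.info("mutant LRC %d exceeds wild-type LRC %d; summation bound "
                    "extended", mut.lrc, bound)
        bound = mut.lrc
    value = 0.0
    for i in sorted(set(wt.counts) | set(mut.counts)):
        if i > bound:
            continue
        diff = wt.get(i) - mut.get(i)
        if diff:
            value += i * scheme.weight(i, wt) * diff
    return RDScore(value=value, scheme=scheme.name)
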