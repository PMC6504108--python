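"""Turn simulated profiles into measured pattern quantities.

The wet-lab readouts this mirrors are in-situ stain patterns scored by eye:
which stretches of the medial otic edge express a marker ("domains"), how
far expression reaches as a percentage of the edge length ("extent"), and
whether anterior expression dominates posterior expression.  A profile is
"expressing" where it exceeds a detection threshold, by default 20% of the
species' saturation level — the stain-visibility cutoff is a convention, not
something the data pin down.

``run_concordance`` scores a batch of simulated scenarios against a suite
of staged qualitative observations shipped as a data file, one assertion
per observation, each carrying its own anchor text.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .scenario_engine import Kymograph, sample_stage

__all__ = [
    "ExpressionDomain",
    "ConcordanceAssertion",
    "ConcordanceReport",
    "call_domains",
    "extent_percent",
    "asymmetry_index",
    "load_suite",
    "default_suite_path",
    "run_concordance",
    "DETECTION_FRACTION",
    "MIN_DOMAIN_WIDTH",
]

#: detection threshold as a fraction of the species saturation level
DETECTION_FRACTION = 0.2
#: minimum domain width (fraction of axis); suppresses solver ripples
MIN_DOMAIN_WIDTH = 0.05

PREDICATES = (
    "extent_ge",
    "extent_le",
    "domain_count_eq",
    "graded_decreasing",
    "anterior_gt_posterior",
    "level_ratio_ge",
    "level_ratio_le",
    "extent_ge_ref",
)


@dataclass(frozen=True)
class ExpressionDomain:
    """A contiguous above-threshold interval of a profile."""

    start: float
    end: float
    peak_level: float
    mean_level: float
    peak_position: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.start < self.end <= 1.0 + 1e-12:
            raise ValueError("domain bounds must satisfy 0 <= start < end <= 1")
        if not self.peak_level >= self.mean_level - 1e-12 or self.mean_level <= 0.0:
            raise ValueError("require peak_level >= mean_level > 0")

    @property
    def width(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ConcordanceAssertion:
    """One staged qualitative observation, evaluated on a simulated profile."""

    id: str
    scenario: str
    species: str
    stage: float
    predicate: str
    argument: float
    ref_scenario: str = ""
    anchor: str = ""

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise ValueError(
                f"unknown predicate {self.predicate!r}; valid: {PREDICATES}"
            )


@dataclass(frozen=True)
class ConcordanceReport:
    entries: tuple  # (assertion, measured value, passed)
    fraction_passed: float

    @property
    def all_passed(self) -> bool:
        return self.fraction_passed == 1.0

    def to_text(self) -> str:
        lines = ["# id\tscenario\tspecies\tstage_hpf\tpredicate\targument"
                 "\tmeasured\tverdict\tanchor"]
        for a, measured, ok in self.entries:
            lines.append(
                f"{a.id}\t{a.scenario}\t{a.species}\t{a.stage:g}\t"
                f"{a.predicate}\t{a.argument:g}\t{measured:.4g}\t"
                f"{'pass' if ok else 'FAIL'}\t{a.anchor}"
            )
        lines.append(f"# fraction_passed\t{self.fraction_passed:.4f}")
        return "\n".join(lines) + "\n"


def _check_profile(profile: np.ndarray) -> np.ndarray:
    profile = np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(profile)):
        raise ValueError("profile contains non-finite values")
    return profile


def call_domains(
    positions: Sequence[float],
    profile: Sequence[float],
    threshold: float,
    min_width: float = MIN_DOMAIN_WIDTH,
) -> list[ExpressionDomain]:
    """Segment a profile into above-threshold expression domains.

    Maximal runs of grid points with value >= threshold, merged across
    single-point dips (one-point closing), then discarded if narrower than
    ``min_width``.  Bounds are the grid positions of the run endpoints.
    """
    x = np.asarray(positions, dtype=float)
    v = _check_profile(profile)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    spacing = float(np.min(np.diff(x)))
    if min_width < spacing - 1e-12:
        raise ValueError("min_width must be at least the grid spacing")

    above = v >= threshold
    # one-point closing: a single sub-threshold sample between two
    # above-threshold samples is discretisation noise, not a real gap
    closed = above.copy()
    interior = ~above[1:-1] & above[:-2] & above[2:]
    closed[1:-1] |= interior

    domains: list[ExpressionDomain] = []
    i = 0
    n = len(x)
    while i < n:
        if not closed[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and closed[j + 1]:
            j += 1
        if x[j] - x[i] >= min_width - 1e-12:
            seg = v[i:j + 1]
            k = int(np.argmax(seg))
            peak = float(seg[k])
            domains.append(ExpressionDomain(
                start=float(x[i]), end=float(x[j]),
                peak_level=peak,
                mean_level=min(float(seg.mean()), peak),
                peak_position=float(x[i + k]),
            ))
        i = j + 1
    return domains


def extent_percent(
    positions: Sequence[float], profile: Sequence[float], threshold: float
) -> float:
    """Above-threshold length as a percentage of the axis.

    The profile is treated as piecewise linear between grid samples, so
    threshold crossings inside a grid cell contribute fractional length.
    """
    x = np.asarray(positions, dtype=float)
    v = _check_profile(profile)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    total = 0.0
    for i in range(len(x) - 1):
        a, b = v[i] - threshold, v[i + 1] - threshold
        dx = x[i + 1] - x[i]
        if a >= 0 and b >= 0:
            total += dx
        elif a >= 0 or b >= 0:
            # linear crossing: fraction of the cell on the positive side
            frac = (a if a >= 0 else b) / abs(a - b)
            total += dx * frac
    return 100.0 * total / (x[-1] - x[0])


def asymmetry_index(
    positions: Sequence[float], profile: Sequence[float]
) -> float:
    """(A - P) / (A + P) over anterior/posterior half means; 0 if all zero."""
    x = np.asarray(positions, dtype=float)
    v = _check_profile(profile)
    ant = v[x < 0.5]
    post = v[x > 0.5]
    a, p = float(ant.mean()), float(post.mean())
    if a + p == 0.0:
        return 0.0
    return (a - p) / (a + p)


def anterior_mean(positions: Sequence[float], profile: Sequence[float]) -> float:
    x = np.asarray(positions, dtype=float)
    return float(_check_profile(profile)[x < 0.5].mean())


def default_suite_path() -> Path:
    return Path(__file__).parent / "data" / "concordance_suite.tsv"


def load_suite(path: str | Path | None = None) -> list[ConcordanceAssertion]:
    """Load a concordance suite from a tab-separated text file."""
    path = Path(path) if path is not None else default_suite_path()
    out: list[ConcordanceAssertion] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = ["id", "scenario", "species", "stage_hpf", "predicate",
              "argument", "ref_scenario", "anchor"]
    for row in rows:
        if row == header:
            continue
        if len(row) != len(header):
            raise ValueError(f"malformed suite row: {row!r}")
        rec = dict(zip(header, row))
        out.append(ConcordanceAssertion(
            id=rec["id"], scenario=rec["scenario"], species=rec["species"],
            stage=float(rec["stage_hpf"]), predicate=rec["predicate"],
            argument=float(rec["argument"]),
            ref_scenario=rec["ref_scenario"], anchor=rec["anchor"],
        ))
    return out


def _profile_for(
    results: Mapping[str, Mapping[str, Kymograph]],
    scenario: str, species: str, stage: float,
) -> tuple[np.ndarray, np.ndarray]:
    if scenario not in results:
        raise KeyError(f"scenario {scenario!r} missing from results")
    if species not in results[scenario]:
        raise KeyError(f"species {species!r} missing for scenario {scenario!r}")
    kymo = results[scenario][species]
    profile, _ = sample_stage(kymo, stage)
    return kymo.positions, profile


def evaluate_assertion(
    assertion: ConcordanceAssertion,
    results: Mapping[str, Mapping[str, Kymograph]],
    threshold: float,
    min_width: float = MIN_DOMAIN_WIDTH,
) -> tuple[float, bool]:
    """Measured value and verdict for a single assertion."""
    a = assertion
    x, v = _profile_for(results, a.scenario, a.species, a.stage)
    if a.predicate == "extent_ge":
        m = extent_percent(x, v, threshold)
        return m, m >= a.argument
    if a.predicate == "extent_le":
        m = extent_percent(x, v, threshold)
        return m, m <= a.argument
    if a.predicate == "domain_count_eq":
        m = float(len(call_domains(x, v, threshold, min_width)))
        return m, m == a.argument
    if a.predicate == "graded_decreasing":
        vmax = float(v.max())
        if vmax == 0.0:
            return 0.0, False
        worst_rise = float(np.max(np.diff(v))) / vmax
        drop = float(v[0] - v[-1]) / vmax
        # monotone within 1% ripple, with a real anterior-to-posterior drop
        return drop, (worst_rise <= 0.01) and (drop >= 0.10)
    if a.predicate == "anterior_gt_posterior":
        m = asymmetry_index(x, v)
        return m, m > 0.0
    if a.predicate in ("level_ratio_ge", "level_ratio_le", "extent_ge_ref"):
        if not a.ref_scenario:
            raise ValueError(f"assertion {a.id} needs a reference scenario")
        xr, vr = _profile_for(results, a.ref_scenario, a.species, a.stage)
        if a.predicate == "extent_ge_ref":
            ref = extent_percent(xr, vr, threshold)
            m = extent_percent(x, v, threshold) / ref if ref > 0 else np.inf
            return m, m >= a.argument
        ref = anterior_mean(xr, vr)
        m = anterior_mean(x, v) / ref if ref > 0 else np.inf
        if a.predicate == "level_ratio_ge":
            return m, m >= a.argument
        return m, m <= a.argument
    raise AssertionError(f"unhandled predicate {a.predicate!r}")


def run_concordance(
    results: Mapping[str, Mapping[str, Kymograph]],
    suite: Iterable[ConcordanceAssertion],
    threshold: float = DETECTION_FRACTION,
    min_width: float = MIN_DOMAIN_WIDTH,
) -> ConcordanceReport:
    """Evaluate every assertion; overall pass requires all of them true."""
    entries = []
    for a in suite:
        measured, ok = evaluate_assertion(a, results, threshold, min_width)
        entries.append((a, measured, ok))
    frac = 1.0 if not entries else sum(ok for *_, ok in entries) / len(entries)
    return ConcordanceReport(entries=tuple(entries), fraction_passed=frac)
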