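"""Plain-text serialisation: kymographs, profiles, domain tables.

All writers go through a temp-file-then-rename so a failed run never leaves
a partial output behind.  Kymograph round-trips preserve full float
precision.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable

import numpy as np

from . import __version__
from .pattern_analysis import ExpressionDomain
from .scenario_engine import Kymograph

__all__ = ["write_kymograph", "read_kymograph", "write_text_atomic",
           "domain_table"]


def write_text_atomic(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Tab-separated matrix: rows are times, columns are axis positions."""
    lines = [
        f"# species\t{kymo.species}",
        f"# scenario\t{kymo.scenario}",
        "# units\ta.u.",
        f"# version\t{__version__}",
        "# positions\t" + "\t".join(f"{x:.17g}" for x in kymo.positions),
    ]
    for t, row in zip(kymo.times, kymo.values):
        lines.append(f"{t:.17g}\t" + "\t".join(f"{v:.17g}" for v in row))
    write_text_atomic(path, "\n".join(lines) + "\n")


def read_kymograph(path: str | Path) -> Kymograph:
    meta: dict[str, str] = {}
    positions: np.ndarray | None = None
    times: list[float] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if line.startswith("#"):
                key = parts[0].lstrip("# ").strip()
                if key == "positions":
                    positions = np.array([float(v) for v in parts[1:]])
                elif len(parts) >= 2:
                    meta[key] = parts[1]
                continue
            if positions is None:
                raise ValueError(f"{path}:{lineno}: data before positions header")
            try:
                values = [float(v) for v in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if len(values) != positions.size + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {positions.size + 1} columns, "
                    f"got {len(values)}"
                )
            times.append(values[0])
            rows.append(values[1:])
    if positions is None or not rows:
        raise ValueError(f"{path}: no kymograph data found")
    return Kymograph(
        species=meta.get("species", ""), times=np.array(times),
        positions=positions, values=np.array(rows),
        scenario=meta.get("scenario", ""), meta=meta,
    )


def domain_table(
    records: Iterable[tuple[str, str, float, ExpressionDomain]]
) -> str:
    """Tab-separated domain table on the unit axis (start inclusive,
    end exclusive, fractions half-open), one row per called domain."""
    lines = ["# scenario\tspecies\tstage_hpf\tstart_fraction\tend_fraction"
             "\tpeak_level\tmean_level"]
    for scenario, species, stage, d in records:
        lines.append(
            f"{scenario}\t{species}\t{stage:g}\t{d.start:.6g}\t{d.end:.6g}"
            f"\t{d.peak_level:.6g}\t{d.mean_level:.6g}"
        )
    return "\n".join(lines) + "\n"
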