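"""Reading failure-time files and writing self-describing fixtures."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .censored import TypeICensoredSample
from .distribution import ParamVector
from .simulate import generate_censored_sample

__all__ = ["read_times", "make_fixture", "write_metadata"]


def read_times(path) -> np.ndarray:
    """Read one positive failure time per row; returns the sorted vector.

    A single non-numeric header line is tolerated.  Nonpositive or
    non-finite entries raise with the offending row number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    values = []
    for row, line in enumerate(lines, start=1):
        s = line.strip().strip(",")
        if not s:
            continue
        try:
            v = float(s)
        except ValueError:
            if row == 1:  # header
                continue
            raise ValueError(f"{path}: row {row}: not a number: {s!r}") from None
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{path}: row {row}: times must be positive, got {v}")
        values.append(v)
    if not values:
        raise ValueError(f"{path}: no failure times found")
    return np.sort(np.array(values))


def make_fixture(theta: ParamVector, n: int, censor_time: float, seed: int,
                 path) -> TypeICensoredSample:
    """Write a simulated Type-I censored sample as CSV plus truth sidecar.

    The sidecar (``<path>.meta.json``) records the generating parameters,
    n, m, T and seed so downstream runs are self-describing.
    """
    path = Path(path)
    sample = generate_censored_sample(theta, n, censor_time, seed=seed)
    lines = ["time"] + [f"{t:.10g}" for t in sample.times]
    path.write_text("\n".join(lines) + "\n")
    meta = {
        "theta": {"alpha": theta.alpha, "beta": theta.beta, "lam": theta.lam},
        "n_total": sample.n_total,
        "m": sample.m,
        "censor_time": None if math.isinf(censor_time) else censor_time,
        "seed": seed,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return sample


def write_metadata(out_dir, record: dict) -> Path:
    """Write the run-metadata record (config echo, seed, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = dict(record)
    record["nexf_version"] = __version__
    p = out_dir / "run_metadata.json"
    p.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return p
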