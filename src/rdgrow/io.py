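"""CSV output of profiles and front traces.

Profiles are written time-major (one block of rows per snapshot, rows in
grid order) with columns ``t, coordinate, position, C``; front traces with
columns ``t, L, f, status``.  Floats are written with ``repr`` precision so
a write/read round trip is bit-identical.
"""

from __future__ import annotations

from typing import List, Sequence

import pandas as pd

from .colonization import FrontTrace
from .exceptions import InputError
from .problem import Profile

__all__ = ["write_profiles", "read_profiles", "write_front_trace", "read_front_trace"]

_PROFILE_COLUMNS = ["t", "coordinate", "position", "C"]


def profiles_frame(profiles: Sequence[Profile]) -> pd.DataFrame:
    """Tidy DataFrame of snapshots, time-major then position order."""
    rows = []
    for p in profiles:
        rows.append(pd.DataFrame({
            "t": p.t,
            "coordinate": p.coordinate,
            "position": p.grid,
            "C": p.values,
        }))
    if not rows:
        return pd.DataFrame(columns=_PROFILE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_profiles(profiles: Sequence[Profile], path) -> None:
    """Write snapshots as CSV; an empty list yields a header-only file."""
    profiles_frame(profiles).to_csv(path, index=False)


def read_profiles(path) -> List[Profile]:
    """Read a profiles CSV back into Profile objects (inverse of write)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"profiles CSV missing column(s): {', '.join(missing)}")
    out: List[Profile] = []
    if df.empty:
        return out
    # preserve file order of (t, coordinate) blocks
    seen = df[["t", "coordinate"]].drop_duplicates()
    for t, coord in seen.itertuples(index=False):
        block = df[(df["t"] == t) & (df["coordinate"] == coord)]
        out.append(Profile(t=float(t), coordinate=str(coord),
                           grid=block["position"].to_numpy(),
                           values=block["C"].to_numpy()))
    return out


def write_front_trace(trace: FrontTrace, path) -> None:
    """Write a front trace as CSV with columns t, L, f, status."""
    pd.DataFrame({
        "t": trace.times,
        "L": trace.lengths,
        "f": trace.fronts,
        "status": trace.statuses,
    }).to_csv(path, index=False)


def read_front_trace(path, epsilon: float = float("nan")) -> FrontTrace:
    """Read a front-trace CSV written by :func:`write_front_trace`."""
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("t", "L", "f", "status"):
        if c not in df.columns:
            raise InputError(f"front-trace CSV missing column {c!r}")
    return FrontTrace(times=df["t"].to_numpy(), lengths=df["L"].to_numpy(),
                      fronts=df["f"].to_numpy(), statuses=list(df["status"]),
                      epsilon=epsilon)
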