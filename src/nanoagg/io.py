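"""Text readers/writers for the package's file formats.

All formats are whitespace-delimited text with '#'-prefixed unit
headers, '.' decimal separator, scientific notation allowed.  Writers
use 17 significant digits so write/read round-trips preserve data to
full double precision.

Formats
-------
PMF curve    : 2 columns (d_nm, G_kJ_per_mol)
table        : 3 columns (d_nm, U_kJ_per_mol, F_kJ_per_mol_nm); header
               records step, r_c, R, afe
trajectory   : XYZ; comment line carries time (ps) and box edge (nm)
kinetics     : TSV (time_us, n_clusters, mean_size); header records
               n_total
config       : flat key = value lines
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .clusters import KineticsTrace
from .potentials import PMFCurve, TabulatedPotential

__all__ = [
    "read_pmf_curve", "write_pmf_curve",
    "read_table", "write_table",
    "read_traj", "write_traj",
    "read_trace", "write_trace",
    "write_histograms",
    "read_config",
]

_FMT = "%.17g"


def _parse_header_meta(path):
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].replace(",", " ").split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
    return meta


def _load_columns(path, n_cols):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from None
    return np.asarray(rows, dtype=float)


def write_pmf_curve(path, curve: PMFCurve) -> None:
    with open(path, "w") as fh:
        fh.write(f"# PMF curve R_nm={_FMT % curve.radius}\n")
        fh.write("# columns: d_nm G_kJ_per_mol\n")
        for d, g in zip(curve.distances, curve.energies):
            fh.write(f"{_FMT % d} {_FMT % g}\n")


def read_pmf_curve(path, radius: float | None = None) -> PMFCurve:
    meta = _parse_header_meta(path)
    if radius is None:
        radius = meta.get("R_nm")
    if radius is None:
        raise ValueError(f"{path}: no R_nm in header and no radius given")
    data = _load_columns(path, 2)
    return PMFCurve(data[:, 0], data[:, 1], float(radius))


def write_table(path, table: TabulatedPotential) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# tabulated potential "
            f"step_nm={_FMT % table.step} r_c_nm={_FMT % table.r_c} "
            f"R_nm={_FMT % table.radius} afe_kJ_mol={_FMT % table.afe}\n"
        )
        fh.write("# columns: d_nm U_kJ_per_mol F_kJ_per_mol_nm\n")
        for d, u, f in zip(table.distances, table.energy, table.force):
            fh.write(f"{_FMT % d} {_FMT % u} {_FMT % f}\n")


def read_table(path) -> TabulatedPotential:
    meta = _parse_header_meta(path)
    data = _load_columns(path, 3)
    if data.shape[0] < 2:
        raise ValueError(f"{path}: table needs at least two rows")
    d = data[:, 0]
    step = meta.get("step_nm", float(d[1] - d[0]))
    spacing = np.diff(d)
    if not np.allclose(spacing, step, rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: non-uniform grid does not match declared step")
    return TabulatedPotential(
        step=float(step), d_min=float(d[0]), d_max=float(d[-1]),
        energy=data[:, 1], force=data[:, 2],
        radius=float(meta.get("R_nm", np.nan)),
        afe=float(meta.get("afe_kJ_mol", np.nan)),
        r_c=float(meta.get("r_c_nm", np.nan)),
    )


def write_traj(path, trajectory) -> None:
    """Write frames as XYZ; comment line: t_ps=<time> box_nm=<edge>."""
    with open(path, "w") as fh:
        for k in range(len(trajectory)):
            pos = trajectory.positions[k]
            fh.write(f"{pos.shape[0]}\n")
            fh.write(
                f"t_ps={_FMT % trajectory.times[k]} box_nm={_FMT % trajectory.h_box}\n"
            )
            for x, y, z in pos:
                fh.write(f"NP {_FMT % x} {_FMT % y} {_FMT % z}\n")


def read_traj(path):
    """Read an XYZ trajectory -> (list of (time_ps, positions), h_box)."""
    frames = []
    h_box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise ValueError(f"{path}:{k + 1}: expected atom count") from None
        comment = lines[k + 1]
        meta = {}
        for token in comment.replace("#", " ").split():
            if "=" in token:
                key, _, val = token.partition("=")
                meta[key] = float(val)
        t = meta.get("t_ps", 0.0)
        h_box = meta.get("box_nm", h_box)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{k + 3 + i}: malformed XYZ row")
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append((t, pos))
        k += 2 + n
    return frames, h_box


def write_trace(path, trace: KineticsTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kinetics trace n_total={_FMT % trace.n_total}\n")
        fh.write("# columns: time_us n_clusters mean_size\n")
        for t, nc, ms in zip(trace.times, trace.n_clusters, trace.mean_size):
            fh.write(f"{_FMT % t}\t{_FMT % nc}\t{_FMT % ms}\n")


def read_trace(path) -> KineticsTrace:
    meta = _parse_header_meta(path)
    data = _load_columns(path, 3)
    n_total = meta.get("n_total")
    if n_total is None:
        n_total = float(data[0, 1] * data[0, 2])
    return KineticsTrace(
        times=data[:, 0], n_clusters=data[:, 1], mean_size=data[:, 2],
        n_total=float(n_total),
    )


def write_histograms(path, trace: KineticsTrace) -> None:
    """Per-frame cluster-size histograms: rows (time_us, size, count)."""
    with open(path, "w") as fh:
        fh.write("# columns: time_us cluster_size count\n")
        for t, hist in zip(trace.times, trace.histograms):
            for size, count in enumerate(hist):
                if size > 0 and count > 0:
                    fh.write(f"{_FMT % t}\t{size}\t{count}\n")


_CONFIG_KEYS = {
    "radius", "mass", "phi", "n", "box", "dt", "temperature", "mu",
    "steps", "stride", "seed", "table", "min_gap", "skin",
    "rebuild_interval",
}


def read_config(path) -> dict:
    """Flat key = value simulation config; unknown keys are rejected."""
    cfg = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, val = body.partition("=")
            key = key.strip()
            val = val.strip()
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown config key '{key}'")
            if key == "table":
                cfg[key] = val
            elif key in {"n", "steps", "stride", "seed", "rebuild_interval"}:
                cfg[key] = int(val)
            else:
                cfg[key] = float(val)
    return cfg


def _ensure_parent(path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
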