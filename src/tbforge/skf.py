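"""Reader/writer for the dftb.org .skf Slater-Koster file format.

Both dialects are supported: homonuclear files carry an extra second line
with on-site eigenvalues (Ed Ep Es), SPE, Hubbard values (Ud Up Us) and
occupations (fd fp fs); heteronuclear files go straight to the mass line.
The optional "Spline" block stores the repulsive potential as an
exponential head, cubic segments, and a 5th-order terminal segment.
"""

from __future__ import annotations

import numpy as np

from .repulsive import RepulsivePotential
from .twocenter import SKF_CHANNELS, SlaterKosterTable


class SkfParseError(ValueError):
    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _fmt(x: float) -> str:
    return f"{x: .12e}"


def write_skf(table: SlaterKosterTable, path) -> None:
    """Serialize a table (values in hartree/bohr, as the format requires)."""
    homonuclear = table.pair[0] == table.pair[1]
    lines = []
    lines.append(f"{table.step:.12f} {table.n_points + 1:d}")
    if homonuclear:
        ons = [table.onsite.get(l, 0.0) for l in (2, 1, 0)]
        hub = [table.hubbard.get(l, table.hubbard.get(0, 0.0)) for l in (2, 1, 0)]
        occ = [table.occupations.get(l, 0.0) for l in (2, 1, 0)]
        lines.append(
            " ".join(_fmt(v) for v in (*ons, 0.0, *hub, *occ))
        )
    lines.append(
        " ".join([_fmt(table.mass)] + [_fmt(0.0)] * 19)
    )
    # row i corresponds to r = i * step, i = 1..n; the first tabulated
    # distance is table.start which must equal step
    if abs(table.start - table.step) > 1e-12:
        raise ValueError(
            ".skf requires the distance grid to start at one grid spacing"
        )
    for i in range(table.n_points):
        row = []
        for kind in ("h", "s"):
            arrs = table.h if kind == "h" else table.s
            for ch in SKF_CHANNELS:
                v = arrs.get(ch)
                row.append(v[i] if v is not None else 0.0)
        lines.append(" ".join(_fmt(v) for v in row))
    rep = table.repulsive
    if rep is not None:
        lines.append("Spline")
        nint = len(rep.knots) - 1
        lines.append(f"{nint:d} {rep.cutoff:.12f}")
        lines.append(" ".join(_fmt(c) for c in rep.exp_coeffs))
        for i in range(nint):
            a, b = rep.knots[i], rep.knots[i + 1]
            c = list(rep.coefficients[i])
            want = 6 if i == nint - 1 else 4
            c = c + [0.0] * (want - len(c))
            lines.append(
                f"{a:.12f} {b:.12f} " + " ".join(_fmt(x) for x in c[:want])
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_skf(path, pair=None) -> SlaterKosterTable:
    """Parse a .skf file.  ``pair`` (symA, symB) is taken from the filename
    (e.g. Zr-O.skf) when not given explicitly."""
    if pair is None:
        import os, re

        stem = os.path.splitext(os.path.basename(path))[0]
        m = re.match(r"([A-Z][a-z]?)[-_]([A-Z][a-z]?)$", stem)
        pair = (m.group(1), m.group(2)) if m else ("X", "X")
    homonuclear = pair[0] == pair[1]

    with open(path) as fh:
        raw = fh.read().splitlines()
    lines = [ln for ln in raw if ln.strip()]
    idx = 0

    def next_line():
        nonlocal idx
        if idx >= len(lines):
            raise SkfParseError(path, idx, "unexpected end of file")
        ln = lines[idx]
        idx += 1
        return ln, idx

    ln, no = next_line()
    head = ln.replace(",", " ").split()
    try:
        step = float(head[0])
        n_grid = int(head[1])
    except (ValueError, IndexError):
        raise SkfParseError(path, no, f"bad grid header {ln!r}")

    onsite, hubbard, occupations = {}, {}, {}
    ln, no = next_line()
    vals = [float(x) for x in ln.replace(",", " ").split()]
    if homonuclear:
        if len(vals) < 10:
            raise SkfParseError(
                path, no, "homonuclear file lacks the eigenvalue header line"
            )
        onsite = {2: vals[0], 1: vals[1], 0: vals[2]}
        hubbard = {2: vals[4], 1: vals[5], 0: vals[6]}
        occupations = {2: vals[7], 1: vals[8], 0: vals[9]}
        ln, no = next_line()
        vals = [float(x) for x in ln.replace(",", " ").split()]
    else:
        if len(vals) == 10:
            raise SkfParseError(
                path, no,
                "heteronuclear file carries a homonuclear eigenvalue line",
            )
    mass = vals[0]

    n_points = n_grid - 1
    H = {ch: np.zeros(n_points) for ch in SKF_CHANNELS}
    S = {ch: np.zeros(n_points) for ch in SKF_CHANNELS}
    for i in range(n_points):
        ln, no = next_line()
        if ln.strip().lower().startswith("spline"):
            raise SkfParseError(
                path, no,
                f"table ended early: header promises {n_grid} rows "
                f"(grid spacing x row count inconsistent with spline start)",
            )
        row = [float(x) for x in ln.replace(",", " ").split()]
        if len(row) < 20:
            raise SkfParseError(path, no, f"expected 20 columns, got {len(row)}")
        for j, ch in enumerate(SKF_CHANNELS):
            H[ch][i] = row[j]
            S[ch][i] = row[10 + j]

    # drop all-zero channels (absent angular momenta)
    H = {ch: v for ch, v in H.items() if np.any(v != 0.0)}
    S = {ch: v for ch, v in S.items() if np.any(v != 0.0)}

    rep = None
    while idx < len(lines):
        ln, no = next_line()
        if ln.strip().lower() == "spline":
            ln, no = next_line()
            parts = ln.split()
            nint, cutoff = int(parts[0]), float(parts[1])
            ln, no = next_line()
            a1, a2, a3 = (float(x) for x in ln.split()[:3])
            knots, coeffs = [], []
            for i in range(nint):
                ln, no = next_line()
                parts = [float(x) for x in ln.split()]
                start, end = parts[0], parts[1]
                c = parts[2:]
                if i == 0:
                    knots.append(start)
                knots.append(end)
                if i < nint - 1 and len(c) < 4:
                    raise SkfParseError(path, no, "cubic segment needs 4 coeffs")
                if i == nint - 1 and len(c) < 6:
                    raise SkfParseError(path, no, "terminal segment needs 6 coeffs")
                coeffs.append(np.array(c))
            if abs(knots[-1] - cutoff) > 1e-8:
                raise SkfParseError(path, no, "spline cutoff mismatch")
            rep = RepulsivePotential(
                knots=np.array(knots), coefficients=coeffs,
                exp_coeffs=(a1, a2, a3),
            )
            break

    table = SlaterKosterTable(
        pair=tuple(pair), start=step, step=step, n_points=n_points,
        h=H, s=S, onsite=onsite, hubbard=hubbard,
        occupations=occupations, mass=mass, repulsive=rep,
    )
    return table
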