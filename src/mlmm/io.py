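"""File formats.

Two plain-text dialects are used throughout:

* **XYZ** for ML regions — ``element x y z`` (Å), multi-frame by
  concatenation.  The comment line may carry ``key=value`` tokens;
  recognised keys are ``charge`` (total formal charge) and ``labels``
  (comma-separated per-atom names, e.g. ``labels=C10,C11,H12``).  Files
  without a ``labels`` token get default ``element + 1-based index`` labels.
* **Point-charge XYZ** for MM environments — the same layout with columns
  ``element x y z charge [sigma epsilon]``; charge in elementary units,
  Lennard-Jones sigma in Å and epsilon in kcal/mol.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .core import MLRegion, MMEnvironment


def write_table(path, df) -> None:
    """CSV writer for reference tables; floats round-trip bit-exactly."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path):
    import pandas as pd

    return pd.read_csv(path, float_precision="round_trip")


def _parse_comment(comment: str) -> dict:
    out = {}
    for token in comment.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def _read_blocks(text: str):
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        body = lines[i + 2 : i + 2 + n]
        if len(body) != n:
            raise ValueError("truncated XYZ frame")
        yield comment, [ln.split() for ln in body]
        i += 2 + n


def read_xyz(path) -> list[MLRegion]:
    """Read a (multi-frame) XYZ file into a list of :class:`MLRegion`."""
    text = Path(path).read_text()
    frames = []
    for comment, rows in _read_blocks(text):
        meta = _parse_comment(comment)
        elements = [r[0] for r in rows]
        coords = np.array([[float(x) for x in r[1:4]] for r in rows])
        labels = meta["labels"].split(",") if "labels" in meta else None
        charge = int(meta.get("charge", 0))
        frames.append(
            MLRegion(elements, coords, total_charge=charge, atom_labels=labels)
        )
    return frames


def write_xyz(path, regions: MLRegion | list[MLRegion]) -> None:
    if isinstance(regions, MLRegion):
        regions = [regions]
    buf = _io.StringIO()
    for region in regions:
        buf.write(f"{region.n_atoms}\n")
        labels = ",".join(region.atom_labels)
        buf.write(f"charge={region.total_charge} labels={labels}\n")
        for el, xyz in zip(region.elements, region.coordinates):
            buf.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
    Path(path).write_text(buf.getvalue())


def read_pointcharge_xyz(path) -> list[MMEnvironment]:
    """Read the point-charge dialect into a list of :class:`MMEnvironment`."""
    text = Path(path).read_text()
    frames = []
    for _comment, rows in _read_blocks(text):
        coords = np.array([[float(x) for x in r[1:4]] for r in rows])
        charges = np.array([float(r[4]) for r in rows])
        if all(len(r) >= 7 for r in rows):
            sigma = np.array([float(r[5]) for r in rows])
            eps = np.array([float(r[6]) for r in rows])
        else:
            sigma = eps = None
        frames.append(MMEnvironment(coords, charges, sigma, eps))
    return frames


def write_pointcharge_xyz(path, envs: MMEnvironment | list[MMEnvironment],
                          element: str = "X") -> None:
    if isinstance(envs, MMEnvironment):
        envs = [envs]
    buf = _io.StringIO()
    for env in envs:
        buf.write(f"{env.n_atoms}\npoint charges\n")
        for p, q, s, e in zip(env.positions, env.charges,
                              env.lj_sigma, env.lj_epsilon):
            buf.write(
                f"{element} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f} "
                f"{q:.10f} {s:.10f} {e:.10f}\n"
            )
    Path(path).write_text(buf.getvalue())
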