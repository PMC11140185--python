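"""Pattern serialization and run manifests.

A pattern on disk is a directory with ``pattern.npz`` (64-bit ``u`` and
``v`` arrays) and a JSON sidecar ``meta.json`` carrying provenance (model,
parameters, seed, dx, boundary tag, residual, stop reason).  CSV export is
available for human inspection.  Array coordinates follow the convention
row = y index, column = x index, origin at the top-left of the stored
array.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .simulate import Pattern

__all__ = ["write_pattern", "read_pattern", "export_csv", "write_manifest",
           "PatternIntegrityError"]


class PatternIntegrityError(RuntimeError):
    """Grid file and sidecar metadata disagree or are unreadable."""


def write_pattern(pattern: Pattern, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "pattern.npz", u=pattern.u.astype(np.float64),
             v=pattern.v.astype(np.float64))
    meta = dict(pattern.meta, dx=float(pattern.dx), bc=pattern.bc,
                n=int(pattern.n))
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_pattern(path) -> Pattern:
    path = Path(path)
    npz = path / "pattern.npz" if path.is_dir() else path
    if not npz.exists():
        raise FileNotFoundError(f"no pattern file at {npz}")
    try:
        with np.load(npz) as data:
            u, v = data["u"], data["v"]
    except Exception as e:
        raise PatternIntegrityError(f"unreadable pattern file {npz}: {e}") from e
    sidecar = npz.parent / "meta.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("n") is not None and meta["n"] != u.shape[0]:
            raise PatternIntegrityError(
                f"sidecar says n={meta['n']} but grids are {u.shape}")
        dx = float(meta.get("dx", 1.0))
        bc = meta.get("bc", "noflux")
    else:
        warnings.warn(f"missing sidecar {sidecar}; assuming dx=1, no-flux "
                      "boundaries", RuntimeWarning)
        meta, dx, bc = {}, 1.0, "noflux"
    return Pattern(u=u, v=v, dx=dx, bc=bc, meta=meta)


def export_csv(pattern: Pattern, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "u.csv", pattern.u, delimiter=",")
    np.savetxt(out / "v.csv", pattern.v, delimiter=",")


def write_manifest(out_dir, **entries) -> Path:
    """Record the fully resolved configuration of a run next to its outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    p = out / "manifest.json"
    p.write_text(json.dumps(entries, indent=2, default=default))
    return p
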