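"""Complex DEER time traces: container, text I/O, and synthetic generation.

The on-disk format is plain delimited text (tab default, comma accepted):
'#'-prefixed header lines carry metadata as ``key = value``, followed by two
or three numeric columns ``t_us  real  [imag]``. Time is in µs with t = 0 at
the dipolar zero time; negative times are allowed and expected for the
symmetric traces of polarized DEER.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DeerTrace", "read_trace", "write_trace", "synthesize_trace"]


@dataclass
class DeerTrace:
    """A complex echo-amplitude trace on a signed time axis.

    Attributes
    ----------
    t : ndarray
        Time axis, µs, strictly increasing, >= 2 points.
    re, im : ndarray
        In-phase and out-of-phase channel amplitudes.
    meta : dict
        Free-form metadata (field, temperature, pB, cB, source, ...).
    """

    t: np.ndarray
    re: np.ndarray
    im: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.re = np.asarray(self.re, dtype=float)
        self.im = np.asarray(self.im, dtype=float)
        if not (self.t.shape == self.re.shape == self.im.shape):
            raise ValueError("t, re, im must have equal length")
        if self.t.size < 2:
            raise ValueError("trace must contain at least 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("non-monotonic time axis")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.re))
                and np.all(np.isfinite(self.im))):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.t.size

    @property
    def V(self) -> np.ndarray:
        """Complex amplitude re + i·im."""
        return self.re + 1j * self.im

    @classmethod
    def from_complex(cls, t, V, meta=None) -> "DeerTrace":
        V = np.asarray(V, dtype=complex)
        return cls(t=np.asarray(t, dtype=float), re=V.real.copy(),
                   im=V.imag.copy(), meta=dict(meta or {}))


def read_trace(path, format_hint: str | None = None) -> DeerTrace:
    """Read a delimited-text trace file.

    Header lines beginning with '#' are parsed as ``key = value`` metadata.
    Rows must have 2 (t, re) or 3 (t, re, im) numeric fields; a missing
    imaginary column is filled with zeros and flagged in
    ``meta['im_missing']``.
    """
    meta: dict = {}
    rows: list[tuple[float, ...]] = []
    ncols = None
    delim = {"tsv": "\t", "csv": ","}.get(format_hint or "", None)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([^=]+?)\s*=\s*(.*)$", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            fields = line.split(delim) if delim else re.split(r"[,\t\s]+", line)
            fields = [f for f in fields if f]
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got "
                    f"{len(fields)}"
                )
            try:
                vals = tuple(float(f) for f in fields)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from exc
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(
                    f"{path}: line {lineno}: inconsistent column count"
                )
            rows.append(vals)
    if len(rows) < 2:
        raise ValueError(f"{path}: trace must contain at least 2 points")
    arr = np.array(rows, dtype=float)
    t = arr[:, 0]
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: non-monotonic time axis")
    re_ = arr[:, 1]
    if arr.shape[1] == 3:
        im_ = arr[:, 2]
    else:
        im_ = np.zeros_like(re_)
        meta["im_missing"] = "true"
    return DeerTrace(t=t, re=re_, im=im_, meta=meta)


def write_trace(trace: DeerTrace, path) -> None:
    """Write a trace as tab-separated text at full floating precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in trace.meta.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# columns = t_us\treal\timag\n")
        for ti, ri, ii in zip(trace.t, trace.re, trace.im):
            fh.write(f"{ti:.17g}\t{ri:.17g}\t{ii:.17g}\n")


def synthesize_trace(model, t_grid, noise_sigma: float = 0.0, seed=None) -> DeerTrace:
    """Evaluate a forward model on a grid and add Gaussian channel noise.

    i.i.d. zero-mean Gaussian noise of standard deviation ``noise_sigma`` is
    added independently to the in-phase and out-of-phase channels;
    deterministic under a fixed seed.
    """
    from .fitting import forward_model  # local import to avoid a cycle

    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    v = forward_model(model, t)
    rng = np.random.default_rng(seed)
    re_ = v.real + (rng.normal(0.0, noise_sigma, t.shape) if noise_sigma else 0.0)
    im_ = v.imag + (rng.normal(0.0, noise_sigma, t.shape) if noise_sigma else 0.0)
    meta = {"source": "synthetic", "noise_sigma": noise_sigma, "seed": seed}
    for key, val in vars(model).items():
        meta[f"model_{key}"] = val
    return DeerTrace(t=t, re=np.asarray(re_), im=np.asarray(im_), meta=meta)
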