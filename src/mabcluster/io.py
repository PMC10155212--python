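"""Plain-text I/O for scattering curves and small tables.

Scattering curves travel as whitespace-delimited 2- or 3-column text
(q, I[, sigma_I]) with ``#`` comment headers -- the de facto SAXS ``.dat``
format.  On disk q is in Angstrom^-1; model code works in nm^-1 and the
conversion is an exact factor of 10.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScatteringCurve", "read_dat", "write_dat", "q_invA_to_invnm", "q_invnm_to_invA"]


def q_invA_to_invnm(q):
    """Angstrom^-1 -> nm^-1 (exact factor 10)."""
    return np.asarray(q, dtype=float) * 10.0


def q_invnm_to_invA(q):
    """nm^-1 -> Angstrom^-1 (exact factor 0.1)."""
    return np.asarray(q, dtype=float) / 10.0


@dataclass
class ScatteringCurve:
    """Measured or synthetic scattering intensity on a strictly increasing q grid."""

    q: np.ndarray  # [q_unit]
    I: np.ndarray  # intensity [cm^-1 absolute, or arbitrary]
    sigma: np.ndarray | None = None  # optional 1-sigma uncertainties
    c: float = 0.0  # concentration [mg/mL]; 0 for pure form-factor curves
    scale: str = "absolute"  # "absolute" | "relative"
    q_unit: str = "A^-1"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.I.shape != self.q.shape or not np.all(np.isfinite(self.I)):
            raise ValueError("intensities must be finite and match the q grid")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)

    def normalized(self) -> np.ndarray:
        """Concentration-normalized intensity I(q)/c."""
        if self.c <= 0:
            raise ValueError("curve has no positive concentration")
        return self.I / self.c


def write_dat(curve: ScatteringCurve, path) -> None:
    header = (
        f"# q [{curve.q_unit}]  I [{'cm^-1' if curve.scale == 'absolute' else 'arb'}]"
        f"{'  sigma_I' if curve.sigma is not None else ''}\n"
        f"# concentration_mg_ml = {curve.c}\n"
        f"# scale = {curve.scale}\n"
    )
    cols = [curve.q, curve.I] + ([curve.sigma] if curve.sigma is not None else [])
    body = np.column_stack(cols)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10e")


def read_dat(path) -> ScatteringCurve:
    c, scale, q_unit = 0.0, "absolute", "A^-1"
    rows = []
    opener = open(path) if not isinstance(path, _io.TextIOBase) else path
    with opener as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "concentration_mg_ml" in line:
                    c = float(line.split("=")[1])
                elif "scale" in line:
                    scale = line.split("=")[1].strip()
                elif "q [" in line:
                    q_unit = line.split("[")[1].split("]")[0]
                continue
            rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows, dtype=float)
    sigma = arr[:, 2] if arr.shape[1] > 2 else None
    return ScatteringCurve(q=arr[:, 0], I=arr[:, 1], sigma=sigma, c=c, scale=scale, q_unit=q_unit)
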