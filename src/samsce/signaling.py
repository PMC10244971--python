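"""WUSCHEL and cytokinin concentration fields.

Both signals are point-source exponential gradients evaluated at each
cell's centroid:  [WUS] = [WUS]0·exp(−µ_WUS·r_WUS) and likewise for CK,
where r is the distance from the centroid to the corresponding signal
centre.  Tunica cells (L1, L2) lack cytokinin receptors and keep CK = 0.
Signal centres sit on the vertical axis through the apex at configured
depths expressed in multiples of the mean cell diameter, so their
placement tracks cell size in the mechanical submodel.

The default peak concentrations and decay rates are placeholders for a
calibration that is not reproduced here; they are flagged as such in the
configuration and in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tissue import TUNICA, Tissue


@dataclass
class SignalParams:
    wus0: float = 1.0  # peak concentration, a.u. (placeholder default)
    ck0: float = 1.0  # a.u. (placeholder default)
    mu_wus: float = 0.05  # decay rate, 1/µm (placeholder default)
    mu_ck: float = 0.05  # 1/µm (placeholder default)
    wus_depth_cells: float = 3.0  # centre depth below apex, in mean cell diameters
    ck_depth_cells: float = 5.0

    def validate(self) -> None:
        if min(self.wus0, self.ck0) < 0 or min(self.mu_wus, self.mu_ck) < 0:
            raise ValueError("peaks and decay rates must be non-negative")


def place_signal_centres(
    tissue: Tissue, offsets: tuple[float, float] | None = None, params: SignalParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Place the WUS and CK centres on the apex axis (updates the tissue).

    ``offsets`` are depths below the apex in multiples of the current
    mean cell diameter; defaults come from ``params``.
    """
    if not tissue.cells:
        raise ValueError("cannot place signal centres in an empty tissue")
    if offsets is None:
        params = params or SignalParams()
        offsets = (params.wus_depth_cells, params.ck_depth_cells)
    diam = tissue.mean_cell_diameter()
    apex = tissue.apex
    wus_centre = apex - np.array([0.0, offsets[0] * diam])
    ck_centre = apex - np.array([0.0, offsets[1] * diam])
    pts = np.array([n.position for n in tissue.nodes.values()])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    for name, c in (("WUS", wus_centre), ("CK", ck_centre)):
        if not (np.all(c >= lo - 1e-9) and np.all(c <= hi + 1e-9)):
            warnings.warn(f"{name} signal centre {c} falls outside the tissue bounding box")
    tissue.wus_centre = wus_centre
    tissue.ck_centre = ck_centre
    return wus_centre, ck_centre


def assign_concentrations(tissue: Tissue, params: SignalParams) -> Tissue:
    """Evaluate both gradients at every cell centroid (in place).

    CK is forced to zero in L1 and L2.  Idempotent on a static tissue.
    """
    params.validate()
    if tissue.wus_centre is None or tissue.ck_centre is None:
        place_signal_centres(tissue, params=params)
    for cell in tissue.cells.values():
        c = tissue.cell_centroid(cell.id)
        r_wus = float(np.linalg.norm(c - tissue.wus_centre))
        cell.wus = params.wus0 * np.exp(-params.mu_wus * r_wus)
        if cell.layer in TUNICA:
            cell.ck = 0.0
        else:
            r_ck = float(np.linalg.norm(c - tissue.ck_centre))
            cell.ck = params.ck0 * np.exp(-params.mu_ck * r_ck)
    return tissue
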