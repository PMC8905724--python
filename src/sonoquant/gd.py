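"""Voxelwise Gd-DOTA concentration mapping from quantitative T1 maps.

A gadolinium contrast agent shortens the longitudinal relaxation time T1
in proportion to its local concentration:

    1/T1_post = 1/T1_pre + r1 * C

so with registered pre- and post-contrast T1 maps (in seconds) the
concentration map in mM is

    C = (1/T1_post - 1/T1_pre) / r1

with the longitudinal relaxivity ``r1`` in mM^-1 s^-1 (4.5 for Gd-DOTA at
3 T).  Where the contrast agent has leaked through a disrupted
blood-brain barrier, C is positive; elsewhere it fluctuates around zero
with measurement noise.  Negative concentrations are retained — clipping
them would bias ROI-minus-control differences — and voxels with
nonpositive or missing T1 are propagated as NaN, never as zero.

No smoothing or washout correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .volumes import VolumeGrid, check_congruent

#: Longitudinal relaxivity of Gd-DOTA at 3 T, mM^-1 s^-1.
GD_DOTA_RELAXIVITY = 4.5
#: Molar mass of the gadoterate complex, g/mol.
GD_DOTA_MOLAR_MASS = 558.6


@dataclass
class ConcentrationMap:
    """A Gd concentration volume (mM) plus the inputs it came from."""

    volume: VolumeGrid
    r1: float
    pre_frame: str = ""
    post_frame: str = ""
    n_missing: int = 0

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def gd_concentration_map(
    pre: VolumeGrid, post: VolumeGrid, r1: float = GD_DOTA_RELAXIVITY
) -> ConcentrationMap:
    """Concentration map ``C = (1/T1_post - 1/T1_pre) / r1`` in mM.

    ``pre`` and ``post`` are congruent quantitative T1 maps in seconds.
    Voxels where either T1 is nonpositive or non-finite become NaN and are
    counted in ``n_missing``.
    """
    if r1 <= 0:
        raise ParameterError(f"relaxivity must be positive, got {r1}")
    check_congruent(pre, post)
    t1_pre = np.asarray(pre.data, dtype=float)
    t1_post = np.asarray(post.data, dtype=float)
    valid = np.isfinite(t1_pre) & np.isfinite(t1_post) & (t1_pre > 0) & (t1_post > 0)
    conc = np.full(pre.shape, np.nan)
    conc[valid] = (1.0 / t1_post[valid] - 1.0 / t1_pre[valid]) / r1
    return ConcentrationMap(
        volume=pre.like(conc, frame=f"conc({pre.frame},{post.frame})"),
        r1=r1,
        pre_frame=pre.frame,
        post_frame=post.frame,
        n_missing=int((~valid).sum()),
    )
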