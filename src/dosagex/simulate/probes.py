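"""Synthetic two-probe FISH stacks for 3D locus-distance measurements.

Each nucleus image carries two spot channels (one per probe).  Spot pairs are
planted at a configurable physical separation in a random 3D orientation; with
ploidy 2 (tetraploid hypodermal nuclei have two copies of each homolog pair)
each channel receives two spots.  Spots are separable Gaussians evaluated at
voxel centers, so anisotropic voxel sizes are handled exactly.  The truth
table records planted coordinates in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd

from ..imaging import ImageStack

log = logging.getLogger(__name__)

CHANNEL_A = "probeA"
CHANNEL_B = "probeB"


@dataclass
class ProbeSimParams:
    """Generator settings for two-probe distance stacks.

    separation_um is the true physical distance between the two probes of a
    pair; pairs_per_probe is the number of homolog pairs per nucleus (2 in
    tetraploid nuclei).  genomic_separation_bp is carried as metadata only.
    """

    separation_um: float
    n_nuclei: int = 20
    pairs_per_probe: int = 2
    genomic_separation_bp: int = 1_200_000
    spot_sigma_um: float = 0.12
    amplitude: float = 1000.0
    background: float = 50.0
    noise_sd: float = 8.0
    shape_vox: tuple[int, int, int] = (30, 96, 96)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.25, 0.11, 0.11)  # µm
    seed: int = 0

    def validate(self) -> None:
        if self.separation_um < 0:
            raise ValueError("separation must be >= 0")
        if self.pairs_per_probe < 1:
            raise ValueError("pairs_per_probe must be >= 1")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.spot_sigma_um <= 0 or self.amplitude <= 0:
            raise ValueError("spot sigma and amplitude must be positive")


def _render_spot(data: np.ndarray, center_um: np.ndarray, sigma: float, amplitude: float, vs: np.ndarray) -> None:
    """Add a separable 3D Gaussian (µm units) evaluated at voxel centers."""
    axes = []
    for ax in range(3):
        coords = (np.arange(data.shape[ax]) + 0.5) * vs[ax]
        axes.append(np.exp(-((coords - center_um[ax]) ** 2) / (2 * sigma**2)))
    data += amplitude * axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]


def gen_probe_stack(params: ProbeSimParams) -> tuple[list[ImageStack], pd.DataFrame]:
    """Generate two-channel probe stacks plus planted spot coordinates (µm).

    Spots falling within one voxel of the stack boundary are re-drawn (and the
    redraw is logged).  Truth columns: nucleus_id, pair, channel, z/y/x_um,
    separation_um.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(params.voxel_size, dtype=float)
    extent = np.asarray(params.shape_vox) * vs  # physical size, µm
    margin = 3.0 * params.spot_sigma_um + params.separation_um / 2.0 + vs
    if np.any(extent - 2 * margin <= 0):
        raise ValueError("stack too small for the requested separation")
    min_center_gap = params.separation_um + 1.5  # keeps homolog pairs separable

    stacks: list[ImageStack] = []
    rows = []
    for i in range(params.n_nuclei):
        chan_a = np.full(params.shape_vox, params.background, dtype=np.float64)
        chan_b = np.full(params.shape_vox, params.background, dtype=np.float64)
        centers: list[np.ndarray] = []
        for p in range(params.pairs_per_probe):
            for attempt in range(200):
                c = margin + rng.uniform(size=3) * (extent - 2 * margin)
                if all(np.linalg.norm(c - other) >= min_center_gap for other in centers):
                    break
            else:
                raise RuntimeError("could not place non-overlapping homolog pairs")
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            spot_a = c - u * params.separation_um / 2.0
            spot_b = c + u * params.separation_um / 2.0
            if np.any(spot_a < vs) or np.any(spot_b < vs) or np.any(spot_a > extent - vs) or np.any(spot_b > extent - vs):
                log.info("gen_probe_stack: spot near boundary, re-drawing (nucleus %d)", i)
                continue_redraw = True
            else:
                continue_redraw = False
            if continue_redraw:
                # re-draw the orientation until both spots clear the boundary
                for _ in range(200):
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    spot_a = c - u * params.separation_um / 2.0
                    spot_b = c + u * params.separation_um / 2.0
                    inside = not (
                        np.any(spot_a < vs) or np.any(spot_b < vs)
                        or np.any(spot_a > extent - vs) or np.any(spot_b > extent - vs)
                    )
                    if inside:
                        break
                else:
                    raise RuntimeError("could not place a spot pair inside the stack")
            centers.append(c)
            _render_spot(chan_a, spot_a, params.spot_sigma_um, params.amplitude, vs)
            _render_spot(chan_b, spot_b, params.spot_sigma_um, params.amplitude, vs)
            for channel, coord in ((CHANNEL_A, spot_a), (CHANNEL_B, spot_b)):
                rows.append(
                    {
                        "nucleus_id": i,
                        "pair": p,
                        "channel": channel,
                        "z_um": coord[0],
                        "y_um": coord[1],
                        "x_um": coord[2],
                        "separation_um": params.separation_um,
                    }
                )
        data = np.stack([chan_a, chan_b])
        if params.noise_sd > 0:
            data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
        stacks.append(
            ImageStack(
                data=data.astype(np.float32),
                voxel_size=tuple(vs),
                channels=(CHANNEL_A, CHANNEL_B),
            )
        )
    return stacks, pd.DataFrame(rows)
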