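"""Synthetic nuclei with a planted chromosome territory.

Each nucleus is an ellipsoid of bright DNA-counterstain signal on an
anisotropic voxel grid; the chromosome paint channel lights up a connected
sub-region (a spherical cap in physical coordinates) whose voxel count is the
requested fraction of the nucleus voxel count, up to discretization.  The
truth table records the exact realized occupancy per nucleus, so parameter
recovery can be asserted against construction rather than against a noisy
pipeline output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..imaging import ImageStack

DNA_CHANNEL = "dna"
PAINT_CHANNEL = "paint"


@dataclass
class NucleusSimParams:
    """Generator settings for paint-FISH nuclei.

    occupancy is the true territory fraction of nuclear volume (0-1);
    occupancy_sd adds optional between-nucleus biological spread (same units).
    snr is the in-signal / background intensity ratio; noise_sd is additive
    Gaussian noise in intensity units (background level is 100).
    """

    occupancy: float
    n_nuclei: int = 20
    radii_vox: tuple[float, float, float] = (14.0, 22.0, 22.0)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.25, 0.13, 0.13)  # µm
    snr: float = 8.0
    noise_sd: float = 25.0
    background: float = 100.0
    occupancy_sd: float = 0.0
    radius_jitter: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.occupancy < 1.0:
            raise ValueError(f"occupancy must be in (0,1), got {self.occupancy}")
        if min(self.radii_vox) < 4:
            raise ValueError(f"nucleus radii must be >= 4 voxels, got {self.radii_vox}")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.snr <= 1:
            raise ValueError("snr must exceed 1")
        if self.noise_sd < 0 or self.occupancy_sd < 0:
            raise ValueError("noise_sd and occupancy_sd must be >= 0")


def gen_nucleus_stack(params: NucleusSimParams) -> tuple[list[ImageStack], pd.DataFrame]:
    """Generate paint-FISH nucleus stacks plus the per-nucleus truth table.

    Returns ``(stacks, truth)`` where truth has columns nucleus_id,
    planted_pct, realized_pct, n_nucleus_voxels, n_territory_voxels.
    Deterministic for identical params (including seed).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(params.voxel_size, dtype=float)
    stacks: list[ImageStack] = []
    rows = []

    for i in range(params.n_nuclei):
        jitter = 1.0 + rng.uniform(-params.radius_jitter, params.radius_jitter, size=3)
        radii = np.maximum(np.asarray(params.radii_vox) * jitter, 4.0)
        shape = tuple(int(np.ceil(2 * r)) + 7 for r in radii)
        center = (np.asarray(shape) - 1) / 2.0
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        norm = (
            ((zz - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((xx - center[2]) / radii[2]) ** 2
        )
        nucleus = norm <= 1.0
        n_vox = int(nucleus.sum())

        occ = params.occupancy
        if params.occupancy_sd > 0:
            occ = float(np.clip(rng.normal(occ, params.occupancy_sd), 1e-4, 1 - 1e-4))
        k = int(round(occ * n_vox))
        if k < 1 or k >= n_vox:
            raise ValueError(
                f"occupancy {occ:.4f} unrealizable in a nucleus of {n_vox} voxels"
            )
        # territory = spherical cap: the k nucleus voxels furthest along a
        # random direction in *physical* space — connected by construction
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        phys = np.stack(
            [(zz - center[0]) * vs[0], (yy - center[1]) * vs[1], (xx - center[2]) * vs[2]],
            axis=-1,
        )
        depth = phys @ u
        depth_in = np.where(nucleus, depth, -np.inf)
        flat = depth_in.ravel()
        cut_idx = np.argpartition(flat, -k)[-k:]
        territory = np.zeros(nucleus.size, dtype=bool)
        territory[cut_idx] = True
        territory = territory.reshape(nucleus.shape)

        realized = 100.0 * k / n_vox
        signal = params.background * params.snr
        dna = np.where(nucleus, signal, params.background).astype(np.float32)
        paint = np.where(territory, signal, params.background).astype(np.float32)
        data = np.stack([dna, paint])
        if params.noise_sd > 0:
            data = data + rng.normal(0.0, params.noise_sd, size=data.shape).astype(np.float32)
        stacks.append(
            ImageStack(
                data=data.astype(np.float32),
                voxel_size=tuple(vs),
                channels=(DNA_CHANNEL, PAINT_CHANNEL),
            )
        )
        rows.append(
            {
                "nucleus_id": i,
                "planted_pct": 100.0 * occ,
                "realized_pct": realized,
                "n_nucleus_voxels": n_vox,
                "n_territory_voxels": k,
            }
        )

    return stacks, pd.DataFrame(rows)
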