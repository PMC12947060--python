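"""HDF5 container for sinogram stacks and bin masks.

Schema (version 1): datasets ``sinogram`` (float32, plane x radial x
angular), ``bin_mask/surviving_fraction`` (float64), ``bin_mask/affected``
(uint8), optional ``crystal_mask`` (uint8, rings x crystals); root attributes
``schema_version``, ``n_rings``, ``n_crystals_per_ring``, ``n_radial``,
``n_angles``, ``max_ring_difference``, ``summed_rd1``, ``provenance`` and
optionally ``pattern``.  Plane ordering is the segment-major order of
:mod:`sparsepet.binning`.
"""

from __future__ import annotations

import numpy as np

import h5py

from .binning import BinMask, MichelogramScheme, SinogramStack
from .geometry import CrystalMask, ScannerGeometry

__all__ = ["SCHEMA_VERSION", "write_stack", "read_stack", "SchemaError"]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Missing dataset or incompatible container version."""


def write_stack(
    path,
    stack: SinogramStack,
    mask: BinMask | None = None,
    crystal_mask: CrystalMask | None = None,
    pattern: str | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_rings"] = stack.scheme.n_rings
        f.attrs["max_ring_difference"] = stack.scheme.max_ring_difference
        f.attrs["summed_rd1"] = stack.scheme.summed_rd1
        f.attrs["n_radial"] = stack.n_radial
        f.attrs["n_angles"] = stack.n_angles
        f.attrs["provenance"] = stack.provenance
        if pattern is not None:
            f.attrs["pattern"] = pattern
        if crystal_mask is not None:
            f.attrs["n_crystals_per_ring"] = crystal_mask.geometry.n_crystals_per_ring
            f.create_dataset("crystal_mask", data=crystal_mask.kept.astype(np.uint8))
        else:
            f.attrs["n_crystals_per_ring"] = 2 * stack.n_angles
        f.create_dataset("sinogram", data=stack.data.astype(np.float32))
        if mask is not None:
            g = f.create_group("bin_mask")
            g.create_dataset("surviving_fraction", data=mask.surviving_fraction)
            g.create_dataset("affected", data=mask.affected.astype(np.uint8))


def read_stack(path, require_mask: bool = True):
    """Read (stack, mask) from a container; ``mask`` is None when absent and
    not required."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema version {version} (expected {SCHEMA_VERSION})"
            )
        if "sinogram" not in f:
            raise SchemaError("missing dataset 'sinogram'")
        scheme = MichelogramScheme(
            n_rings=int(f.attrs["n_rings"]),
            max_ring_difference=int(f.attrs["max_ring_difference"]),
            summed_rd1=bool(f.attrs["summed_rd1"]),
        )
        stack = SinogramStack(
            f["sinogram"][...].astype(np.float64), scheme, str(f.attrs["provenance"])
        )
        mask = None
        if "bin_mask" in f:
            mask = BinMask(f["bin_mask/surviving_fraction"][...], scheme)
        elif require_mask:
            raise SchemaError("missing group 'bin_mask'")
    return stack, mask
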