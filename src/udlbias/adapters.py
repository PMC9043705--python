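"""Adapters mapping external data deposits onto the canonical schema.

The study's deposited trial data (Dryad, doi:10.6078/D1MX4P) can be
analyzed with this package once mapped to the canonical
``trials.csv``/``trajectories.csv`` layout. The deposit's on-disk
layout is not vendored here; implement the mapping below against a
local download.
"""
from __future__ import annotations

from .generate import SimulatedDataset

DRYAD_DOI = "10.6078/D1MX4P"


def load_dryad(path: str) -> SimulatedDataset:
    """Map a local copy of the Dryad deposit to the canonical schema.

    Parameters
    ----------
    path : str
        Directory holding the downloaded deposit.

    Returns
    -------
    SimulatedDataset
        Trial table plus 200 Hz trajectories in the canonical frame
        (start circle at the origin, positions in cm, angles in
        degrees), ready for :func:`udlbias.kinematics.reduce_dataset`.

    Notes
    -----
    This is a deliberate stub: the mapping depends on the deposit's
    file layout, which is not distributed with the package.
    """
    raise NotImplementedError(
        f"implement the mapping from the Dryad deposit ({DRYAD_DOI}) "
        "at %r to the canonical trials/trajectories schema" % path)
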