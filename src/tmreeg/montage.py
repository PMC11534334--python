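"""19-channel 10-10 montage used throughout: channel names and sensor adjacency.

The adjacency is a hand-curated nearest-neighbour relation over the standard
scalp layout (rows Fp / F / C / P / O plus the temporal chain), used by the
cluster-based permutation test to decide which channels may join a cluster.
"""

from __future__ import annotations

import numpy as np

#: The 19 EEG channels retained for analysis, in canonical order.
CHANNELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
)

# Neighbour lists over the scalp grid (symmetrised below).
_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F7", "F3", "Fz"),
    "Fp2": ("Fp1", "F8", "F4", "Fz"),
    "F7": ("Fp1", "F3", "T7"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T8"),
    "T7": ("F7", "C3", "P7"),
    "C3": ("F3", "T7", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T8", "Cz", "P4"),
    "T8": ("F8", "C4", "P8"),
    "P7": ("T7", "P3", "O1"),
    "P3": ("C3", "P7", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "P8", "Pz", "O2"),
    "P8": ("T8", "P4", "O2"),
    "O1": ("P7", "P3", "Pz", "O2"),
    "O2": ("P8", "P4", "Pz", "O1"),
}


def montage_adjacency() -> dict[str, frozenset[str]]:
    """Symmetric, irreflexive channel adjacency for the 19-channel montage."""
    adj: dict[str, set[str]] = {ch: set() for ch in CHANNELS_19}
    for ch, nbrs in _NEIGHBORS.items():
        for nb in nbrs:
            if nb == ch:
                continue
            adj[ch].add(nb)
            adj[nb].add(ch)
    return {ch: frozenset(nbrs) for ch, nbrs in adj.items()}


def adjacency_matrix(channels: list[str] | tuple[str, ...]) -> np.ndarray:
    """Boolean (n, n) adjacency matrix restricted to ``channels`` (in order).

    Channels outside the montage get no neighbours.
    """
    adj = montage_adjacency()
    n = len(channels)
    mat = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(channels):
        for j, b in enumerate(channels):
            if i != j and b in adj.get(a, frozenset()):
                mat[i, j] = True
    return mat


def normalize_channel_label(label: str) -> str:
    """Case-insensitive match of ``label`` against the montage; unknown labels verbatim."""
    lut = {ch.lower(): ch for ch in CHANNELS_19}
    return lut.get(label.strip().lower(), label.strip())
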