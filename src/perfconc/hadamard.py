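"""Hadamard time-encoding of pCASL sub-boli.

In a time-encoded acquisition the labeling period is split into N−1
sub-boli whose label/control states follow the sign pattern of a Sylvester
Hadamard matrix; a "free-lunch" scheme gives the first sub-bolus a long
labeling duration so that the scheme embeds a conventional single-delay
acquisition at no extra scan time. Decoding each sub-bolus's
perfusion-weighted image is a signed linear combination of the N encoded
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard as _sylvester

__all__ = ["HadamardScheme", "hadamard_matrix", "hadamard_timing", "free_lunch_scheme"]


def hadamard_matrix(n_encode: int) -> np.ndarray:
    """N × (N−1) ±1 encoding matrix from the Sylvester construction.

    The all-ones column of the Sylvester matrix is dropped (it carries the
    static signal, not a sub-bolus). Entry +1 means the sub-bolus is in the
    label state for that volume; the first encoded volume labels every
    sub-bolus. Columns are orthogonal and individually sum to zero.
    """
    n = int(n_encode)
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"N must be a power of 2 and ≥ 2, got {n_encode}")
    full = _sylvester(n)
    return full[:, 1:].astype(int)


@dataclass(frozen=True)
class HadamardScheme:
    """Timing and encoding of an N-volume time-encoded pCASL scheme.

    ``sub_bolus_durations`` (ms) are ordered from the earliest (first
    labeled) sub-bolus to the last; in a free-lunch scheme the first entry
    is the long labeling duration. ``final_pld`` is the delay between the
    end of the last sub-bolus and the readout.
    """

    n_encode: int
    sub_bolus_durations: tuple[float, ...]
    final_pld: float
    encoding_matrix: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        n = int(self.n_encode)
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"N must be a power of 2, got {self.n_encode}")
        durs = tuple(float(d) for d in self.sub_bolus_durations)
        if len(durs) != n - 1:
            raise ValueError(f"expected {n - 1} sub-bolus durations, got {len(durs)}")
        if any(d <= 0 for d in durs):
            raise ValueError("sub-bolus durations must be positive")
        if self.final_pld < 0:
            raise ValueError("final PLD must be non-negative")
        object.__setattr__(self, "sub_bolus_durations", durs)
        mat = self.encoding_matrix
        if mat is None:
            mat = hadamard_matrix(n)
        mat = np.asarray(mat)
        if mat.shape != (n, n - 1):
            raise ValueError(f"encoding matrix must be {n}×{n - 1}, got {mat.shape}")
        gram = mat.T @ mat
        if not np.array_equal(gram, n * np.eye(n - 1, dtype=int)):
            raise ValueError("encoding matrix columns must be orthogonal with norm² = N")
        if np.any(mat.sum(axis=0) != 0):
            raise ValueError("each encoding column must sum to zero")
        object.__setattr__(self, "encoding_matrix", mat)


def hadamard_timing(scheme: HadamardScheme) -> tuple[np.ndarray, np.ndarray]:
    """Effective (PLD, LD) per sub-bolus, ms, ordered earliest first.

    The effective post-labeling delay of sub-bolus k is the final PLD plus
    the summed durations of all later sub-boli: for the N=8 free-lunch
    scheme (2000 ms then six 250 ms sub-boli, final PLD 200 ms) this gives
    PLDs 1700, 1450, 1200, 950, 700, 450, 200 ms.
    """
    durs = np.asarray(scheme.sub_bolus_durations, dtype=float)
    # sum of durations strictly after each sub-bolus
    tail = np.concatenate([np.cumsum(durs[::-1])[::-1][1:], [0.0]])
    plds = scheme.final_pld + tail
    return plds, durs.copy()


def free_lunch_scheme(
    n_encode: int = 8,
    free_lunch_ld: float = 2000.0,
    sub_bolus_duration: float = 250.0,
    final_pld: float = 200.0,
) -> HadamardScheme:
    """The free-lunch scheme with a long first sub-bolus; defaults give the
    N = 8 acquisition with PLD₁/LD₁ = 1700/2000 ms and LD₂₋₇ = 250 ms."""
    durs = (free_lunch_ld,) + (sub_bolus_duration,) * (n_encode - 2)
    return HadamardScheme(n_encode=n_encode, sub_bolus_durations=durs, final_pld=final_pld)
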