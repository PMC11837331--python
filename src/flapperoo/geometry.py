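"""Wing geometry for a two-segment (armwing + handwing) flapping wing.

The wing is modelled as a rigid inner segment (armwing, shoulder to wrist)
and an outer segment (handwing, wrist to tip) that folds ventrally about a
chordwise axis through the wrist.  Blade elements discretize each half-wing
along the span; the left/right wings are mirror images, so a single
half-wing is computed and doubled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WingGeometry"]


@dataclass(frozen=True)
class WingGeometry:
    """Planform and discretization of one half-wing.

    Parameters
    ----------
    armwing_length : float
        Shoulder-to-wrist span, m.
    handwing_length : float
        Wrist-to-tip span ``b``, m.  The reference area uses only the
        handwing (the armwing frame carries no membrane): ``S = 2 b c``.
    chord : float
        Wing chord ``c``, m (constant along the span).
    n_elements : int
        Number of blade elements per half-wing (>= 4).
    air_density : float
        Air density ``rho``, kg m^-3.
    """

    armwing_length: float = 0.1
    handwing_length: float = 0.1
    chord: float = 0.2
    n_elements: int = 20
    air_density: float = 1.2

    def __post_init__(self) -> None:
        for name in ("armwing_length", "handwing_length", "chord", "air_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_elements < 4:
            raise ValueError(f"n_elements must be >= 4, got {self.n_elements}")

    @property
    def reference_area(self) -> float:
        """Membrane reference area S = 2 b c (both handwings), m^2."""
        return 2.0 * self.handwing_length * self.chord

    @property
    def total_span(self) -> float:
        """Shoulder-to-tip length of one half-wing, m."""
        return self.armwing_length + self.handwing_length

    def element_grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Blade-element centres along one half-wing.

        Elements are allocated to the two segments in proportion to their
        length, with the wrist always falling on an element boundary so no
        element straddles the fold axis.

        Returns
        -------
        r : ndarray
            Element-centre radial positions from the shoulder, m.
        dr : ndarray
            Element span widths, m; sums exactly to the half-wing length.
        is_handwing : ndarray of bool
            True for elements outboard of the wrist.
        """
        total = self.total_span
        n_arm = int(round(self.n_elements * self.armwing_length / total))
        n_arm = min(max(n_arm, 1), self.n_elements - 1)
        n_hand = self.n_elements - n_arm
        arm_edges = np.linspace(0.0, self.armwing_length, n_arm + 1)
        hand_edges = np.linspace(self.armwing_length, total, n_hand + 1)
        edges = np.concatenate([arm_edges, hand_edges[1:]])
        r = 0.5 * (edges[:-1] + edges[1:])
        dr = np.diff(edges)
        is_handwing = r > self.armwing_length
        return r, dr, is_handwing
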