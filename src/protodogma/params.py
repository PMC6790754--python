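"""Run parameterization for the protocell simulator.

The model world is a population of protocells, each holding replicators of
two types (P and Q) and substrate particles (S).  The total particle number
``n_tot`` is conserved.  Parameters follow the conventions of the
multilevel-selection protocell model: ``V`` is the cell-division threshold,
``m`` the per-entry mutation probability at each birth, ``d`` the per-step
decay probability, ``delta_mut`` the half-width of the uniform additive
mutation step, and ``k_max`` the (reflecting) upper bound on catalytic
activities.  Defaults place ``n_tot = 50 V`` so that the quasi-stationary
protocell count is about 100 regardless of ``V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["Params"]


@dataclass
class Params:
    """Parameters of one simulation run.

    Raises
    ------
    ValueError
        If any invariant is violated (``V >= 2``, ``0 <= m <= 1``,
        ``0 < d <= 1``, ``delta_mut > 0``, ``k_max > 0``, cadences ``>= 1``).
    """

    V: int = 100
    m: float = 0.01
    d: float = 0.02
    delta_mut: float = 0.05
    k_max: float = 1.0
    n_tot: int | None = None  # defaults to 50*V
    init_cells: int = 50
    t_max: int = 10_000
    record_every: int = 1000
    snapshot_every: int = 0  # 0 = only initial and final snapshots
    seed: int = 0
    log_genealogy: bool = True
    log_mutations: bool = False

    def __post_init__(self) -> None:
        if self.n_tot is None:
            self.n_tot = 50 * self.V
        self.validate()

    def validate(self) -> None:
        if self.V < 2:
            raise ValueError(f"V must be >= 2, got {self.V}")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if not 0.0 < self.d <= 1.0:
            raise ValueError(f"d must be in (0, 1], got {self.d}")
        if self.delta_mut <= 0.0:
            raise ValueError(f"delta_mut must be > 0, got {self.delta_mut}")
        if self.k_max <= 0.0:
            raise ValueError(f"k_max must be > 0, got {self.k_max}")
        if self.init_cells < 1:
            raise ValueError(f"init_cells must be >= 1, got {self.init_cells}")
        if self.n_tot < self.init_cells:
            raise ValueError(
                f"n_tot ({self.n_tot}) must be >= init_cells ({self.init_cells})"
            )
        if self.t_max < 0:
            raise ValueError(f"t_max must be >= 0, got {self.t_max}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")
        if self.snapshot_every < 0:
            raise ValueError(f"snapshot_every must be >= 0, got {self.snapshot_every}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)
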