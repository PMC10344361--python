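"""Simulation presets for a panel of clinically observed single deletions.

Each preset pairs deletion breakpoints with the orthogonally measured
(Southern blot / qPCR) heteroplasmy fraction used as the simulated truth.
``del6`` is excluded: its printed coordinates and size are mutually
inconsistent (15,573 - 11,570 = 4,003, not 6,997), so it cannot be
simulated without silently "fixing" one of the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .refgenome import BAMHI, PVUII, RestrictionEnzyme
from .simulate import Deletion

__all__ = ["DeletionPreset", "PRESETS", "ENZYMES"]


@dataclass(frozen=True)
class DeletionPreset:
    name: str
    deletion: Deletion
    fraction: float  # heteroplasmy measured by Southern blot / qPCR
    size: int

    def __post_init__(self) -> None:
        assert (self.deletion.end - self.deletion.start) % 16_569 == self.size


PRESETS: dict[str, DeletionPreset] = {
    p.name: p
    for p in [
        DeletionPreset("del1", Deletion(7_634, 13_956), 0.50, 6_322),
        DeletionPreset("del2", Deletion(8_482, 13_446), 0.35, 4_964),
        DeletionPreset("del3", Deletion(7_343, 15_602), 0.40, 8_259),
        DeletionPreset("del4", Deletion(10_955, 15_544), 0.50, 4_589),
        DeletionPreset("del5", Deletion(8_482, 13_460), 0.50, 4_978),
        DeletionPreset("del7", Deletion(7_829, 14_826), 0.50, 6_997),
        DeletionPreset("del8", Deletion(12_714, 15_862), 0.50, 3_148),
        DeletionPreset("del9", Deletion(6_341, 14_005), 0.30, 7_664),
    ]
}

ENZYMES: dict[str, RestrictionEnzyme] = {"BamHI": BAMHI, "PvuII": PVUII}
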