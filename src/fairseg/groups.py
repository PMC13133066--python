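"""Protected-group vocabulary and seeded random substreams.

The fairness analysis partitions patients along two binary protected
attributes, race (White / Black) and gender (Male / Female), giving four
intersectional subgroups: MW, MB, FW, FB.  Every sample in a dataset maps
to exactly one of them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

RACES = ("White", "Black")
GENDERS = ("Male", "Female")


@dataclass(frozen=True, order=True)
class GroupKey:
    """One intersectional race-gender subgroup."""

    race: str
    gender: str

    def __post_init__(self):
        if self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}; expected one of {RACES}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}; expected one of {GENDERS}")

    @property
    def code(self) -> str:
        """Short gender-race label as used in clinical demographics tables (MB, FW, ...)."""
        return self.gender[0] + self.race[0]

    @classmethod
    def from_code(cls, code: str) -> "GroupKey":
        gender = {"M": "Male", "F": "Female"}[code[0]]
        race = {"W": "White", "B": "Black"}[code[1]]
        return cls(race, gender)


#: Canonical cycling order for demographic interleaving and quota allocation.
GROUP_ORDER: tuple[GroupKey, ...] = (
    GroupKey("White", "Male"),
    GroupKey("White", "Female"),
    GroupKey("Black", "Male"),
    GroupKey("Black", "Female"),
)

SITES = ("A", "B", "C", "D", "E")
SPLITS = ("train", "val", "test")


def substream(seed: int, *names: object) -> np.random.Generator:
    """Derive a named, independent random generator from a master seed.

    Every component (image generation, splitting, site assignment, DP noise,
    per-epoch shuffles, ...) draws from its own substream so that re-seeding
    one of them never perturbs the others.  The stream key is the master seed
    followed by CRC32 hashes of the name parts, which keeps each entry well
    below 2**32 as required by ``SeedSequence``.
    """
    key = [int(seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(key))


def group_of(race: str, gender: str) -> GroupKey:
    return GroupKey(race, gender)
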