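"""Core domain types for landmark-based wing morphometrics.

A specimen is represented by an ordered configuration of k two-dimensional
landmarks (wing-vein intersections) plus identifying metadata.  Datasets are
homogeneous collections of such configurations; downstream modules consume
them as (n, k, 2) coordinate arrays with aligned metadata columns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Species(str, enum.Enum):
    """Species label; the study system is a two-species discrimination."""

    JAPONICUS = "japonicus"
    KOREICUS = "koreicus"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Species":
        """Map free-text species strings (case/space-insensitive) to the enum.

        Any string containing 'japonicus' maps to JAPONICUS, 'koreicus' to
        KOREICUS; everything else is UNKNOWN.
        """
        v = str(value).strip().lower()
        if "japonicus" in v:
            return cls.JAPONICUS
        if "koreicus" in v:
            return cls.KOREICUS
        return cls.UNKNOWN


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Sex":
        v = str(value).strip().lower()
        if v in ("female", "f"):
            return cls.FEMALE
        if v in ("male", "m"):
            return cls.MALE
        return cls.UNKNOWN


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized landmarks plus metadata.

    coords is a (k, 2) float array in input units (pixels, or physical units
    if a TPS SCALE factor was applied on read).  replicate indexes repeated
    digitizations of the same wing (>= 1).
    """

    specimen_id: str
    coords: np.ndarray
    species: Species = Species.UNKNOWN
    sex: Sex = Sex.UNKNOWN
    observer: str = "obs1"
    site: str | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be a (k, 2) array, got shape {self.coords.shape}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        self.species = Species(self.species)
        self.sex = Sex(self.sex)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def key(self) -> tuple[str, str, int]:
        """Uniqueness key within a dataset."""
        return (self.specimen_id, self.observer, self.replicate)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkConfiguration):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and self.species == other.species
            and self.sex == other.sex
            and self.observer == other.observer
            and self.site == other.site
            and self.replicate == other.replicate
            and self.coords.shape == other.coords.shape
            and np.allclose(self.coords, other.coords, rtol=0.0, atol=1e-9)
        )


@dataclass
class LandmarkDataset:
    """Homogeneous collection of landmark configurations."""

    configurations: list[LandmarkConfiguration]
    provenance: str = ""
    _k: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset must contain at least one configuration")
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(
                f"heterogeneous landmark counts in dataset: {sorted(ks)}"
            )
        self._k = ks.pop()

    @property
    def landmark_count(self) -> int:
        assert self._k is not None
        return self._k

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkDataset):
            return NotImplemented
        return (
            len(self) == len(other)
            and all(a == b for a, b in zip(self, other))
        )

    def coords_array(self) -> np.ndarray:
        """All raw coordinates stacked as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def metadata_frame(self) -> pd.DataFrame:
        """Per-specimen metadata as a DataFrame aligned with coords_array."""
        return pd.DataFrame(
            {
                "id": [c.specimen_id for c in self.configurations],
                "species": [c.species.value for c in self.configurations],
                "sex": [c.sex.value for c in self.configurations],
                "observer": [c.observer for c in self.configurations],
                "site": [c.site for c in self.configurations],
                "replicate": [c.replicate for c in self.configurations],
            }
        )

    def subset(self, mask) -> "LandmarkDataset":
        """New dataset with the configurations selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self),):
            raise ValueError("mask length must equal dataset size")
        kept = [c for c, m in zip(self.configurations, mask) if m]
        if not kept:
            raise ValueError("subset selects no configurations")
        return LandmarkDataset(kept, provenance=self.provenance)
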