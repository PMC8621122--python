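"""Named anatomical landmarks in world coordinates (mm).

Landmarks are attached to a bone label so they can follow that bone's rigid
motion through a dynamic sequence.  On disk they are plain CSV with columns
``name,label,x,y,z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Landmark", "LandmarkSet", "read_landmarks", "write_landmarks"]


@dataclass
class Landmark:
    name: str
    bone_label: int
    position: np.ndarray  # world mm, shape (3,)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"landmark '{self.name}': position must be 3-D")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"landmark '{self.name}': position must be finite")


@dataclass
class LandmarkSet:
    entries: list[Landmark] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate landmark names: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> Landmark:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"no landmark named '{name}'")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def positions(self) -> np.ndarray:
        """(n, 3) array of positions in entry order."""
        if not self.entries:
            return np.zeros((0, 3))
        return np.stack([e.position for e in self.entries])

    def subset(self, bone_label: int) -> "LandmarkSet":
        return LandmarkSet([e for e in self.entries if e.bone_label == bone_label])

    def with_positions(self, positions: np.ndarray) -> "LandmarkSet":
        """Same names/labels with replaced positions (entry order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.entries), 3):
            raise ValueError("positions shape mismatch")
        return LandmarkSet(
            [Landmark(e.name, e.bone_label, p) for e, p in zip(self.entries, positions)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "label": [e.bone_label for e in self.entries],
                "x": [e.position[0] for e in self.entries],
                "y": [e.position[1] for e in self.entries],
                "z": [e.position[2] for e in self.entries],
            }
        )


_REQUIRED_COLUMNS = ("name", "label", "x", "y", "z")


def read_landmarks(path: str) -> LandmarkSet:
    """Read landmarks from CSV with header ``name,label,x,y,z``."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file '{path}' missing columns: {missing}")
    entries = [
        Landmark(str(row["name"]), int(row["label"]), np.array([row.x, row.y, row.z]))
        for _, row in df.iterrows()
    ]
    return LandmarkSet(entries)


def write_landmarks(landmarks: LandmarkSet, path: str) -> None:
    """Write landmarks to CSV, preserving coordinates to full precision."""
    landmarks.to_frame().to_csv(path, index=False, float_format="%.17g")
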