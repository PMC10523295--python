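"""Leukocyte class labels.

The classifier distinguishes the four most prevalent granulocyte/agranulocyte
types in stained peripheral-blood smears: eosinophil, lymphocyte, monocyte and
neutrophil. Basophils (under 1% of circulating leukocytes) are excluded, so a
``basophil`` label anywhere in a manifest is an error, not a fifth class.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Fixed alphabetical class order; index i in every confusion matrix,
#: probability vector and one-hot target refers to CLASS_NAMES[i].
CLASS_NAMES: tuple[str, ...] = ("eosinophil", "lymphocyte", "monocyte", "neutrophil")


@dataclass(frozen=True, order=True)
class CellClass:
    """One of the four leukocyte classes, with its fixed alphabetical index."""

    index: int
    name: str

    def __post_init__(self) -> None:
        if self.name not in CLASS_NAMES:
            raise ValueError(
                f"unknown cell class {self.name!r}; valid classes are {list(CLASS_NAMES)}"
            )
        if CLASS_NAMES[self.index] != self.name:
            raise ValueError(
                f"class index {self.index} does not match name {self.name!r} "
                f"(expected index {CLASS_NAMES.index(self.name)})"
            )

    @classmethod
    def from_name(cls, name: str) -> "CellClass":
        key = str(name).strip().lower()
        if key not in CLASS_NAMES:
            raise ValueError(
                f"unknown cell class {name!r}; valid classes are {list(CLASS_NAMES)}"
            )
        return cls(CLASS_NAMES.index(key), key)

    @classmethod
    def from_index(cls, index: int) -> "CellClass":
        if not 0 <= index < len(CLASS_NAMES):
            raise ValueError(f"class index must be in [0, {len(CLASS_NAMES)}), got {index}")
        return cls(index, CLASS_NAMES[index])

    @classmethod
    def all(cls) -> tuple["CellClass", ...]:
        return tuple(cls(i, n) for i, n in enumerate(CLASS_NAMES))
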