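"""Ordered class catalogues for mutually exclusive segmentation problems.

A catalogue fixes the set of foreground classes, their channel order (stable
for a whole run: channel ``i`` of every target, logit and probability stack
refers to ``foreground_names[i]``) and a distinguished background identifier
that is never a foreground class.
"""
from __future__ import annotations

from dataclasses import dataclass


class CatalogError(ValueError):
    """An identifier is unknown to, or inconsistent with, a catalogue."""


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered foreground class identifiers plus a background identifier.

    Parameters
    ----------
    foreground_names
        Unique, non-empty class identifiers.  The index of a name in this
        tuple is its channel index everywhere in the package.
    background_id
        Reserved identifier for "none of the foreground classes"; must not
        collide with a foreground name.  In integer label maps the background
        is encoded as ``len(foreground_names)``.
    """

    foreground_names: tuple[str, ...]
    background_id: str = "background"

    def __init__(self, foreground_names, background_id: str = "background"):
        names = tuple(foreground_names)
        if not names:
            raise CatalogError("catalog needs at least one foreground class")
        if any(not isinstance(n, str) or not n for n in names):
            raise CatalogError("class identifiers must be non-empty strings")
        if len(set(names)) != len(names):
            raise CatalogError(f"duplicate class identifiers in {names!r}")
        if background_id in names:
            raise CatalogError(
                f"background id {background_id!r} collides with a foreground class"
            )
        object.__setattr__(self, "foreground_names", names)
        object.__setattr__(self, "background_id", background_id)

    @property
    def n_foreground(self) -> int:
        return len(self.foreground_names)

    @property
    def background_index(self) -> int:
        """Integer code of the background in label maps."""
        return len(self.foreground_names)

    def index_of(self, name: str) -> int:
        """Channel index of a foreground class (background has no channel)."""
        try:
            return self.foreground_names.index(name)
        except ValueError:
            raise CatalogError(
                f"unknown class {name!r}; catalog has {self.foreground_names}"
            ) from None

    def name_of(self, index: int) -> str:
        """Inverse of :meth:`index_of`; maps the background index too."""
        if index == self.background_index:
            return self.background_id
        if 0 <= index < self.n_foreground:
            return self.foreground_names[index]
        raise CatalogError(f"label index {index} out of range for {self}")

    def __contains__(self, name: str) -> bool:
        return name in self.foreground_names

    def __len__(self) -> int:
        return self.n_foreground
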