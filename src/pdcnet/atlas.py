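"""Cortical region atlas: 14 homotopic left/right pairs of sensorimotor and
association areas retained after source localization.

The canonical ordering places all left-hemisphere regions first, followed by
their right-hemisphere homotopes in the same base order, so that region ``i``
(left) pairs with region ``i + 14`` (right). After hemisphere flipping the
left block always denotes the affected hemisphere of a stroke subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASE_REGIONS: tuple[str, ...] = (
    "CG", "INS", "IPL", "M1", "MFG", "MTG", "Pcun",
    "PoG", "SPL", "STG", "pSTS", "vPM", "SMA", "dorsalA6",
)

LEFT, RIGHT = "L", "R"


def _label(base: str, hemi: str) -> str:
    return f"{base}-{hemi}"


@dataclass(frozen=True)
class RegionAtlas:
    """28-region atlas of homotopic cortical areas.

    Attributes
    ----------
    labels : tuple of str
        Region labels ``"<base>-L"`` / ``"<base>-R"``, left block first.
    hemisphere : tuple of str
        ``"L"`` or ``"R"`` per region.
    """

    labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    hemisphere: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.labels is None:
            labels = tuple(_label(b, LEFT) for b in BASE_REGIONS) + tuple(
                _label(b, RIGHT) for b in BASE_REGIONS
            )
            object.__setattr__(self, "labels", labels)
        if self.hemisphere is None:
            hemis = tuple(lab.rsplit("-", 1)[1] for lab in self.labels)
            object.__setattr__(self, "hemisphere", hemis)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate region labels")
        if len(self.labels) % 2:
            raise ValueError("atlas requires an even number of regions")
        # validate the homotope matching is a perfect left/right pairing
        pairs = self.homotope_pairs
        if len(pairs) != self.n_regions // 2:
            raise ValueError("homotope map is not a perfect matching")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        return self.n_regions // 2

    @property
    def base_names(self) -> tuple[str, ...]:
        return tuple(lab.rsplit("-", 1)[0] for lab in self.labels[: self.n_pairs])

    @property
    def homotope_pairs(self) -> tuple[tuple[int, int], ...]:
        """(left_index, right_index) for each base region."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        pairs = []
        for lab, hemi in zip(self.labels, self.hemisphere):
            if hemi != LEFT:
                continue
            base = lab.rsplit("-", 1)[0]
            mirror = _label(base, RIGHT)
            if mirror not in idx:
                raise ValueError(f"region {lab!r} has no right homotope")
            pairs.append((idx[lab], idx[mirror]))
        return tuple(pairs)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def homotope(self, label: str) -> str:
        base, hemi = label.rsplit("-", 1)
        return _label(base, RIGHT if hemi == LEFT else LEFT)

    def flip_permutation(self):
        """Index permutation that swaps every region with its homotope."""
        import numpy as np

        perm = np.arange(self.n_regions)
        for li, ri in self.homotope_pairs:
            perm[li], perm[ri] = ri, li
        return perm


def default_atlas() -> RegionAtlas:
    return RegionAtlas()
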