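"""Standard 16-channel 10-20 montage and the canonical frequency bands.

The montage order is fixed package-wide: every ``Recording`` and every
feature column index refers to channels in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ordered 16-channel subset of the international 10-20 system.
MONTAGE_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "T3", "T4",
    "T5", "T6", "C3", "C4", "P3", "P4", "O1", "O2",
)

#: Parieto-occipital / posterior-temporal channels, where slowing of the
#: resting rhythm is most pronounced in degenerative dementia.
POSTERIOR_CHANNELS: tuple[str, ...] = ("T5", "T6", "P3", "P4", "O1", "O2")

POSTERIOR_IDX: tuple[int, ...] = tuple(MONTAGE_16.index(c) for c in POSTERIOR_CHANNELS)

OCCIPITAL_IDX: tuple[int, ...] = (MONTAGE_16.index("O1"), MONTAGE_16.index("O2"))


@dataclass(frozen=True)
class BandScheme:
    """Named frequency intervals used for all band-resolved features.

    Intervals are half-open in spirit ([low, high]); adjacent bands share an
    edge frequency, and integration over a band includes both edges, so the
    five bands tile 1-45 Hz exactly.
    """

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "delta": (1.0, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 45.0),
    })

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (lo, hi) in edges:
            if not 0.0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(edges[:-1], edges[1:]):
            if lo2 < hi:
                raise ValueError("band interiors overlap")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]

    def items(self):
        return self.bands.items()


DEFAULT_BANDS = BandScheme()
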