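"""EEG channel layout: 64-channel 10-20 template, hemisphere labels, neighbours.

The template is the standard BioSemi 64-electrode montage shipped with MNE,
projected to 2-D. Midline channels are those whose label contains a lowercase
``z`` (Fpz, AFz, Fz, FCz, Cz, CPz, Pz, POz, Oz, Iz); the remaining channels
split 27/27 between the left and right hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

MIDLINE = "midline"
LEFT = "L"
RIGHT = "R"


@dataclass(frozen=True)
class ChannelLayout:
    """2-D electrode layout with hemisphere labels.

    Attributes
    ----------
    names : tuple of str
        Channel labels (10-20 nomenclature).
    pos : ndarray, shape (n_channels, 2)
        2-D positions (head seen from above, x increasing to the right).
    hemisphere : tuple of str
        One of ``"L"``, ``"R"``, ``"midline"`` per channel.
    """

    names: tuple
    pos: np.ndarray
    hemisphere: tuple

    def __post_init__(self):
        if not (len(self.names) == len(self.hemisphere) == self.pos.shape[0]):
            raise ValueError("inconsistent layout field lengths")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def channels(self, hemisphere: str) -> list:
        """Names of channels in one hemisphere ('L', 'R' or 'midline')."""
        return [n for n, h in zip(self.names, self.hemisphere) if h == hemisphere]

    def subset(self, names) -> "ChannelLayout":
        """Restrict the layout to the given channels (order preserved)."""
        idx = [self.index(n) for n in names]
        return ChannelLayout(
            names=tuple(self.names[i] for i in idx),
            pos=self.pos[idx],
            hemisphere=tuple(self.hemisphere[i] for i in idx),
        )

    def neighbors(self, target_degree: int = 6) -> dict:
        """Spatial neighbour structure from 2-D Euclidean distance.

        The distance threshold is the median over channels of the distance to
        the ``target_degree``-th nearest channel, so the median neighbour
        count is approximately ``target_degree``. Symmetric by construction.
        """
        d = np.linalg.norm(self.pos[:, None, :] - self.pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        kth = np.sort(d, axis=1)[:, target_degree - 1]
        thr = float(np.median(kth)) * (1 + 1e-9)
        out = {}
        for i, name in enumerate(self.names):
            out[name] = [self.names[j] for j in np.where(d[i] <= thr)[0]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": list(self.names),
                "x": self.pos[:, 0],
                "y": self.pos[:, 1],
                "hemisphere": list(self.hemisphere),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def layout_from_frame(df: pd.DataFrame) -> ChannelLayout:
    return ChannelLayout(
        names=tuple(df["channel"]),
        pos=df[["x", "y"]].to_numpy(float),
        hemisphere=tuple(df["hemisphere"]),
    )


def read_layout_tsv(path) -> ChannelLayout:
    return layout_from_frame(pd.read_csv(path, sep="\t"))


@lru_cache(maxsize=1)
def standard_layout() -> ChannelLayout:
    """The 64-channel BioSemi 10-20 template layout."""
    import mne

    montage = mne.channels.make_standard_montage("biosemi64")
    ch_pos = montage.get_positions()["ch_pos"]
    names = tuple(montage.ch_names)
    # project to 2-D: drop the vertical coordinate of the spherical positions
    pos = np.array([ch_pos[n][:2] for n in names], float)
    hemi = tuple(
        MIDLINE if "z" in n else (LEFT if ch_pos[n][0] < 0 else RIGHT) for n in names
    )
    return ChannelLayout(names=names, pos=pos, hemisphere=hemi)


def balanced_subset_layout(n_per_hemisphere: int, n_midline: int = 2) -> ChannelLayout:
    """A reduced, hemispherically balanced layout for small simulations.

    Takes ``n_per_hemisphere`` channels per hemisphere (spread over the
    anterior-posterior axis) plus ``n_midline`` midline channels from the
    standard 64-channel template.
    """
    full = standard_layout()

    def spread(names, k):
        # sort by anterior-posterior coordinate, then pick evenly
        order = sorted(names, key=lambda n: full.pos[full.index(n), 1])
        idx = np.linspace(0, len(order) - 1, k).round().astype(int)
        return [order[i] for i in idx]

    chosen = (
        spread(full.channels(LEFT), n_per_hemisphere)
        + spread(full.channels(RIGHT), n_per_hemisphere)
        + spread(full.channels(MIDLINE), n_midline)
    )
    # keep template ordering
    chosen = [n for n in full.names if n in set(chosen)]
    return full.subset(chosen)
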