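"""Blinded plot rendering and curve anonymization.

Raters mark plateaus on static exported plots rather than an interactive
dashboard.  A plot shows the S-curve and its first-order differences, with
the rolling mean and cubic overlay as optional aids; axis tick values can be
hidden so the rater sees only the shape, never mV or m/s feedback that could
pull marks toward known limits.  Curve identities are anonymized with salted
hashes kept in a sidecar, so sessions can be un-blinded after rating.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .curve import ENormsCurve
from .exceptions import ConfigError

__all__ = ["PlotInfo", "build_figure", "render_enorms_plot", "BlindingMap"]

#: Fixed hash salt for SVG element ids so repeated renders are byte-identical.
_SVG_HASHSALT = "enorms-curve-plot"


@dataclass(frozen=True)
class PlotInfo:
    """What a rendered plot contains, for session logs and tests."""

    path: str
    hide_axes: bool
    n_markers: int
    shows_moving_average: bool
    shows_cubic: bool


def build_figure(
    curve: ENormsCurve,
    hide_axes: bool = True,
    show_moving_average: bool = True,
    show_cubic: bool = True,
    markers: tuple[int, int] | None = None,
    title: str | None = None,
):
    """Assemble the rating figure; returns (fig, value_axis, diff_axis)."""
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(curve.ranks, curve.values, color="tab:blue", lw=1.2, label="sorted values")
    if show_cubic:
        ax.plot(
            curve.ranks,
            curve.cubic_at(curve.ranks),
            color="tab:green",
            lw=1.0,
            ls="--",
            label="cubic overlay (p3)",
        )
    ax2 = ax.twinx()
    ax2.plot(
        curve.ranks[1:],
        curve.diffs,
        color="tab:orange",
        lw=0.5,
        alpha=0.5,
        label="first differences",
    )
    if show_moving_average:
        ax2.plot(
            curve.ranks[1:],
            curve.smoothed_diffs,
            color="tab:red",
            lw=1.0,
            label=f"rolling mean (w={curve.window})",
        )
    if markers is not None:
        for rank in markers:
            ax.axvline(rank, color="black", ls=":", lw=1.0)
    ax.set_xlabel("rank")
    ax.set_ylabel("value")
    ax2.set_ylabel("first difference")
    if title:
        ax.set_title(title)
    if hide_axes:
        ax.set_xticklabels([])
        ax.set_yticklabels([])
        ax2.set_yticklabels([])
        ax.set_xlabel("")
        ax.set_ylabel("")
        ax2.set_ylabel("")
    return fig, ax, ax2


def render_enorms_plot(
    curve: ENormsCurve,
    out_path,
    hide_axes: bool = True,
    show_moving_average: bool = True,
    show_cubic: bool = True,
    markers: tuple[int, int] | None = None,
    title: str | None = None,
) -> PlotInfo:
    """Write a static rating plot (format from the file suffix).

    SVG output is deterministic for identical curve + options: the renderer
    hash salt is pinned and no date metadata is embedded.
    """
    out_path = Path(out_path)
    fig, _, _ = build_figure(
        curve,
        hide_axes=hide_axes,
        show_moving_average=show_moving_average,
        show_cubic=show_cubic,
        markers=markers,
        title=title,
    )
    try:
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
            if out_path.suffix.lower() == ".svg":
                fig.savefig(out_path, metadata={"Date": None})
            else:
                fig.savefig(out_path)
    finally:
        plt.close(fig)
    return PlotInfo(
        path=str(out_path),
        hide_axes=hide_axes,
        n_markers=0 if markers is None else len(markers),
        shows_moving_average=show_moving_average,
        shows_cubic=show_cubic,
    )


class BlindingMap:
    """Bijective curve-id anonymization with a salted-hash code book.

    Codes are short salted SHA-256 digests; the salt lives only in the
    sidecar JSON so a rating session can be un-blinded afterwards.
    ``order`` is a deterministic shuffle of the codes (seeded by the salt)
    for presentation.
    """

    def __init__(self, ids: list[str], salt: str):
        if len(set(ids)) != len(ids):
            raise ConfigError("curve ids must be unique for blinding")
        self.salt = salt
        self.code_for = {i: self._code(i) for i in ids}
        if len(set(self.code_for.values())) != len(ids):  # pragma: no cover
            raise ConfigError("hash collision in blinding codes; change the salt")
        self.id_for = {c: i for i, c in self.code_for.items()}
        seed = int.from_bytes(hashlib.sha256(salt.encode()).digest()[:4], "big")
        order = np.array(sorted(self.code_for.values()))
        np.random.default_rng(seed).shuffle(order)
        self.order = order.tolist()

    def _code(self, curve_id: str) -> str:
        digest = hashlib.sha256((self.salt + curve_id).encode()).hexdigest()
        return digest[:8]

    def blind(self, curve_id: str) -> str:
        return self.code_for[curve_id]

    def unblind(self, code: str) -> str:
        return self.id_for[code]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"salt": self.salt, "codes": self.code_for, "order": self.order},
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path) -> "BlindingMap":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        m = cls(list(d["codes"]), d["salt"])
        return m
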