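"""Shared figure-export plumbing: format resolution and deterministic saving."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

ALLOWED_FORMATS = frozenset({
    "pdf", "svg", "svgz", "png", "tif", "tiff", "jpg", "jpeg",
    "eps", "pgf", "ps", "raw", "rgba", "webp",
})

# stable ids inside SVG output so repeated renders are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "popgenviz"


@dataclass
class RenderResult:
    """Path of the written figure plus an introspectable layout description."""

    path: Path
    layout: dict


def resolve_format(out_path, fmt: Optional[str] = None) -> str:
    """Resolve the output format from an explicit override or the extension."""
    if fmt is None:
        fmt = Path(out_path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ALLOWED_FORMATS:
        allowed = ", ".join(sorted(ALLOWED_FORMATS))
        raise ValueError(
            f"unsupported output format {fmt!r}; allowed formats: {allowed}"
        )
    return fmt


def save_figure(fig, out_path, fmt: Optional[str] = None, dpi: int = 300) -> Path:
    """Save a figure with metadata stripped for reproducible vector output."""
    fmt = resolve_format(out_path, fmt)
    out_path = Path(out_path)
    kwargs = {"format": fmt, "dpi": dpi}
    if fmt == "svg":
        kwargs["metadata"] = {"Date": None}
    elif fmt == "pdf":
        kwargs["metadata"] = {"CreationDate": None}
    elif fmt in ("ps", "eps"):
        kwargs["metadata"] = {"Creator": None}
    fig.savefig(out_path, **kwargs)
    plt.close(fig)
    return out_path
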