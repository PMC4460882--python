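"""Grace-compatible .xvg output.

Plain whitespace-separated numeric columns in fixed 6-significant-digit
scientific notation, preceded by Grace header lines (@ title, @ axis
labels, @ legends) so the files load directly into xmgrace.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["write_xvg"]


def write_xvg(
    path: str | Path,
    x: np.ndarray,
    columns: Sequence[np.ndarray],
    title: str,
    xlabel: str,
    ylabel: str,
    legends: Optional[Sequence[str]] = None,
) -> None:
    x = np.asarray(x, dtype=float)
    cols = [np.asarray(c, dtype=float) for c in columns]
    for c in cols:
        if len(c) != len(x):
            raise ValueError("column length mismatch in xvg output")
    with open(path, "w") as fh:
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis label "{xlabel}"\n')
        fh.write(f'@    yaxis label "{ylabel}"\n')
        fh.write("@TYPE xy\n")
        for i, leg in enumerate(legends or []):
            fh.write(f'@    s{i} legend "{leg}"\n')
        for row in zip(x, *cols):
            fh.write("  ".join(f"{v:.6e}" for v in row) + "\n")
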