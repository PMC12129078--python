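"""A small fully-enumerated worked example.

A hypothetical trial of 36 subjects (18 treated, 18 controls) in which *both*
potential outcomes are written down for every subject — something impossible
in a real study, but exactly what is needed to illustrate, and to test, the
quantities this package estimates.  The example is constructed so the two arms
have identical outcome rates (p0 = p1 = 0.5, no average effect) while a
quarter of the population still benefits from treatment (pi = 0.25).

Among the treated, 9 of 18 respond (Y=1); 6 of those 9 would also have
responded untreated, versus 3 of the 9 non-responders, so A_0 = |6/9 - 3/9| =
0.33.  Symmetrically for the controls, giving A_1 = 0.33.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["worked_example_table", "worked_example_path"]


def worked_example_table() -> pd.DataFrame:
    """The 36-subject table with columns X, Y, Y0, Y1 (Y = Y(X), consistency)."""
    rows = []
    # treated arm: (Y1, Y0) counts 6x(1,1), 3x(1,0), 3x(0,1), 6x(0,0)
    for y1, y0, k in ((1, 1, 6), (1, 0, 3), (0, 1, 3), (0, 0, 6)):
        rows += [(1, y1, y0, y1)] * k
    # control arm: (Y0, Y1) counts 3x(1,1), 6x(1,0), 6x(0,1), 3x(0,0)
    for y0, y1, k in ((1, 1, 3), (1, 0, 6), (0, 1, 6), (0, 0, 3)):
        rows += [(0, y0, y0, y1)] * k
    df = pd.DataFrame(rows, columns=["X", "Y", "Y0", "Y1"])
    df.index += 1
    df.index.name = "subject"
    return df.reset_index()


def worked_example_path():
    """Path to the packaged CSV copy of the worked-example table."""
    return resources.files("benefitsens").joinpath("data", "worked_example.csv")
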