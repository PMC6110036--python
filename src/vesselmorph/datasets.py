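"""Bundled reference tables used by worked examples and regression tests."""

from __future__ import annotations

import pandas as pd

__all__ = ["efficacy_distance_table"]

# Published worked example of a single-factor fuzzy comprehensive evaluation
# of anti-hyperplasia efficacy in a rat balloon-injury study: per-group vector
# distances to the ideal (d_plus) and anti-ideal (d_minus) criterion points,
# with the published closeness grade C (3 dp) and dense rank.  Criteria were
# {HRIA (%), HRIT (%)}; the normal group was not part of the judgement set.
_EFFICACY_ROWS = [
    # group,                    d_plus, d_minus, C,     rank
    ("Model group", 0.502, 0.0, 0.0, 8),
    ("Atorvastatin", 0.045, 0.465, 0.912, 2),
    ("Single Angelica group", 0.106, 0.396, 0.789, 5),
    ("Single Astragalus group", 0.340, 0.164, 0.325, 7),
    ("Astragalus-Angelica 1:2", 0.085, 0.417, 0.831, 3),
    ("Astragalus-Angelica 1:5", 0.086, 0.417, 0.829, 4),
    ("Astragalus-Angelica 1:1", 0.0, 0.502, 1.0, 1),
    ("Astragalus-Angelica 5:1", 0.128, 0.375, 0.746, 6),
    ("Astragalus-Angelica 2:1", 0.340, 0.164, 0.325, 7),
]


def efficacy_distance_table() -> pd.DataFrame:
    """Published distance pairs and closeness grades of the efficacy ranking.

    Columns: ``group``, ``d_plus``, ``d_minus``, ``C`` (published, 3 dp),
    ``rank`` (published dense rank in descending C).
    """
    return pd.DataFrame(
        _EFFICACY_ROWS, columns=["group", "d_plus", "d_minus", "C", "rank"]
    )
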