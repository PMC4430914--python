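"""Synthetic fixture risk charts.

The published WHO/ISH chart cell values are not reproduced here; the
risk engine is chart-agnostic and users transcribe real regional tables
into the CSV dialect.  For a self-contained, licence-clean test bed this
module constructs *synthetic* charts from a simple additive point score
that is monotone in every risk factor:

    score = 2*diabetes + smoker + male + age_index + 2*sbp_index
            [+ tc_index  (HI variant)]

mapped to a band by ``clamp(score - offset, 0, 4)`` with offset 4 (HI)
or 3 (LI).  The HI table is crafted so that the worked on-screen
example — a young male smoker with diabetes, BP 160/89 mmHg, total
cholesterol 176 mg/dL — sits in the top (>=40%) band and drops to the
20-<30% band when systolic pressure falls by one chart band, which is
the transition the risk-projection meter demonstrates.
"""

from __future__ import annotations

from importlib import resources

from .risk import (
    AGE_BANDS,
    SBP_BANDS,
    TC_BANDS,
    ChartTable,
    RiskBand,
    iter_chart_keys,
    load_chart,
    write_chart,
)


def synthetic_chart_score(key) -> int:
    """Additive point score for a chart cell key (shared with tests)."""
    diabetes, gender, smoker, ab, sb, tb = key
    score = 2 * int(diabetes) + int(smoker) + int(gender == "male")
    score += AGE_BANDS.index(ab) + 2 * SBP_BANDS.index(sb)
    if tb is not None:
        score += TC_BANDS.index(tb)
    return score


def synthetic_chart(variant: str, region: str = "synthetic") -> ChartTable:
    """Build the synthetic LI (128-cell) or HI (640-cell) fixture chart."""
    offset = 4 if variant == "HI" else 3
    cells = {
        key: RiskBand(min(4, max(0, synthetic_chart_score(key) - offset)))
        for key in iter_chart_keys(variant)
    }
    return ChartTable(region=region, variant=variant, cells=cells)


def fixture_charts() -> tuple[ChartTable, ChartTable]:
    """The (LI, HI) synthetic fixture charts, built in memory."""
    return synthetic_chart("LI"), synthetic_chart("HI")


def packaged_chart_path(variant: str):
    """Path to the shipped synthetic fixture chart CSV (LI or HI)."""
    name = f"synthetic_chart_{variant.lower()}.csv"
    return resources.files("cvdscreen.data").joinpath(name)


def load_packaged_charts() -> tuple[ChartTable, ChartTable]:
    """Load the shipped synthetic chart CSVs (round-trips the dialect)."""
    with resources.as_file(packaged_chart_path("LI")) as p:
        li = load_chart(p)
    with resources.as_file(packaged_chart_path("HI")) as p:
        hi = load_chart(p)
    return li, hi


def write_fixture_charts(out_dir) -> None:
    """Regenerate the shipped chart CSVs under ``out_dir``."""
    import pathlib

    out = pathlib.Path(out_dir)
    for variant in ("LI", "HI"):
        write_chart(synthetic_chart(variant), out / f"synthetic_chart_{variant.lower()}.csv")


__all__ = [
    "synthetic_chart", "synthetic_chart_score", "fixture_charts",
    "packaged_chart_path", "load_packaged_charts", "write_fixture_charts",
]
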