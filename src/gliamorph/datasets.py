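"""Bundled example tables.

The only dataset shipped with the package is the case-metadata table of a
20-case human post-mortem motor-cortex cohort (10 neurologically normal
controls, 10 ALS cases split into pTDP-43 stage 1-3 and stage 4 subgroups).
It is used by the worked examples and by the demographics summary; no image
data is bundled — images are produced by :mod:`gliamorph.synthetic`.
"""

from __future__ import annotations

import io

import pandas as pd

# case_id, group, stage, age (years), sex, pmd (hours post-mortem delay)
_HUMAN_COHORT_CSV = """\
case_id,group,stage,age,sex,pmd
H211,control,,41,M,8
H215,control,,67,F,23.5
H226,control,,73,F,48
H230,control,,57,F,32
H238,control,,63,F,16
H240,control,,73,M,26.5
H242,control,,61,M,19.5
H245,control,,63,M,20
H247,control,,51,M,31
H249,control,,77,F,17
MN11,ALS,stage1_3,77,F,18
MN14,ALS,stage1_3,59,F,19
MN16,ALS,stage1_3,69,M,16.5
MN20,ALS,stage1_3,85,M,15
MN25,ALS,stage1_3,71,M,23.5
MN13,ALS,stage4,55,M,10
MN15,ALS,stage4,54,F,18
MN19,ALS,stage4,75,M,20.5
MN29,ALS,stage4,72,M,24
MN30,ALS,stage4,84,F,17.5
"""


def human_cohort_demographics() -> pd.DataFrame:
    """Return the example human cohort metadata as a DataFrame.

    Columns: ``case_id``, ``group`` (control / ALS), ``stage`` (pTDP-43
    staging of the ALS cases; empty for controls), ``age`` in years, ``sex``
    (M/F), ``pmd`` post-mortem delay in hours.
    """
    df = pd.read_csv(io.StringIO(_HUMAN_COHORT_CSV), dtype={"stage": "string"})
    df["stage"] = df["stage"].fillna("")
    return df
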