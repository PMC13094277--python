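"""Tagging metadata for the 22 juvenile white sharks monitored through the
August 2023 storm study window (San Diego nursery aggregation).

One row per tagged animal: transmitter family, tagging date, sex, total
length at tagging, the reported age estimate at the time of the storm (from
the von Bertalanffy growth curve) and the total detections logged over the
study window.  Used by the examples and the reproduction script; ages are
recomputed, never read, by the analysis code.
"""

from __future__ import annotations

from datetime import datetime, timezone
from io import StringIO

import pandas as pd

from .telemetry_io import AnimalMetadata

__all__ = ["tagging_table", "tagged_animals", "STORM_DATE"]

#: onset of peak storm conditions (used as the age-reference event date)
STORM_DATE = datetime(2023, 8, 20, tzinfo=timezone.utc)

_TAGGING_CSV = """\
animal_id,tag_family,tagging_date,sex,length_cm,age_at_storm_yr,total_detections
2022-24,V16TP-6x-BLU-2-0204m,2022-06-09,F,213.4,3.3,28940
2022-32,V16P-6x-BLU-2-0204m,2022-06-23,M,243.8,4.3,3
2022-49,V16TP-6x-BLU-2-0204m,2022-08-09,F,213.4,3.2,1449
2022-53,V16P-6x-BLU-2-0204m,2022-08-12,F,213.4,3.1,29474
2022-55,V16P-6x-BLU-2-0204m,2022-08-12,F,243.8,4.1,20433
2022-56,V16P-6x-BLU-2-0204m,2022-08-12,F,182.9,2.2,29310
2022-57,V16P-6x-BLU-2-0204m,2022-08-12,F,213.4,3.1,28020
2022-63,V16P-6x-BLU-2-0204m,2022-09-02,F,243.8,4.1,31865
2022-78,V16P-6x-BLU-2-0204m,2022-09-26,M,213.4,3.0,29323
2022-82,V16P-6x-BLU-2-0204m,2022-10-10,M,213.4,3.0,19441
2022-83,V16P-6x-BLU-2-0204m,2022-10-10,M,213.4,3.0,30085
2023-01,V13AP-1x-BLU-3,2023-06-09,M,213.36,2.3,25837
2023-02,V16P-6x-BLU-2-0204m,2023-06-10,F,213.36,2.3,24392
2023-05,V13AP-1x-BLU-3,2023-07-07,F,198.1,1.8,25093
2023-06,V13AP-1x-BLU-3,2023-07-07,F,213.4,2.2,20828
2023-08,V16P-6x-BLU-2-0204m,2023-07-13,F,243.8,3.2,28989
2023-09,V16P-6x-BLU-2-0204m,2023-07-13,M,182.9,1.3,33264
2023-10,V16P-6x-BLU-2-0204m,2023-07-13,M,198.1,1.8,25239
2023-12,V16P-6x-BLU-2-0204m,2023-07-13,M,213.4,2.2,16265
2023-13,V16P-6x-BLU-2-0204m,2023-07-13,M,198.1,1.8,32918
2023-14,V16P-6x-BLU-2-0204m,2023-07-13,F,243.8,3.2,11169
2023-15,V16P-6x-BLU-2-0204m,2023-07-13,F,198.1,1.8,32263
"""


def tagging_table() -> pd.DataFrame:
    """The tagging summary as a DataFrame (dates parsed to UTC)."""
    df = pd.read_csv(StringIO(_TAGGING_CSV))
    df["tagging_date"] = pd.to_datetime(df["tagging_date"], utc=True)
    return df


def tagged_animals() -> list[AnimalMetadata]:
    """The cohort as :class:`~stormssm.telemetry_io.AnimalMetadata` objects."""
    return [
        AnimalMetadata(
            animal_id=str(r.animal_id),
            sex=str(r.sex),
            length_cm=float(r.length_cm),
            tagging_date=r.tagging_date.to_pydatetime(),
            tag_family=str(r.tag_family),
            age_at_event_yr=float(r.age_at_storm_yr),
        )
        for r in tagging_table().itertuples()
    ]
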