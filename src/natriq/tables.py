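"""Published measurement tables of the 7 T calf-muscle sodium study.

Two tables are shipped as in-code data so the summary statistics and
repeatability analyses can be recomputed without scanner data:

* the relaxometry table — T1, T2*long, T2*short (ms) and the short-component
  partition coefficient (%) per muscle for the four-subject relaxometry
  subgroup;
* the TSC table — tissue sodium concentration (mmol/L, after B0/B1/PVE
  corrections) for 10 healthy subjects x 3 sessions x 3 muscles plus 5
  Addison's-disease patients (single session), GM / TA / S per cell.
"""

from __future__ import annotations

import io

import pandas as pd

MUSCLES = ("GM", "TA", "S")

# subject, muscle, t1 (ms), t2l (ms), t2s (ms), fs (%)
_RELAXOMETRY_CSV = """subject,muscle,t1,t2l,t2s,fs
1,GM,28.5,14.0,3.4,60
1,TA,29.4,12.5,3.1,60
1,S,28.9,14.2,2.5,60
2,GM,24.1,12.6,2.5,60
2,TA,25.4,13.7,3.0,60
2,S,26.0,12.7,4.0,45
3,GM,24.4,11.9,2.7,60
3,TA,26.4,12.2,2.6,55
3,S,27.7,11.0,2.6,60
4,GM,26.4,13.0,5.6,60
4,TA,29.0,12.7,3.9,60
4,S,30.1,13.4,4.5,55
"""

# subject, group, session, GM, TA, S  (TSC in mmol/L)
_TSC_CSV = """subject,group,session,GM,TA,S
1,healthy,M1,20.2,13.4,12.2
1,healthy,M2,21.0,13.2,12.7
1,healthy,M3,20.0,13.2,12.8
2,healthy,M1,20.5,13.7,12.9
2,healthy,M2,20.8,14.0,12.5
2,healthy,M3,20.5,13.2,12.7
3,healthy,M1,19.9,14.6,13.2
3,healthy,M2,19.8,14.8,13.0
3,healthy,M3,19.6,14.6,12.6
4,healthy,M1,20.8,14.0,12.5
4,healthy,M2,20.5,14.5,12.8
4,healthy,M3,20.0,13.9,13.1
5,healthy,M1,20.0,14.9,13.1
5,healthy,M2,19.6,14.0,12.2
5,healthy,M3,19.4,13.5,12.5
6,healthy,M1,19.5,13.8,13.9
6,healthy,M2,20.0,13.1,13.5
6,healthy,M3,20.8,13.7,13.4
7,healthy,M1,19.9,13.5,12.9
7,healthy,M2,19.6,13.6,12.7
7,healthy,M3,19.7,13.3,12.0
8,healthy,M1,19.5,13.7,12.1
8,healthy,M2,19.5,13.0,11.7
8,healthy,M3,19.4,13.5,11.1
9,healthy,M1,19.0,14.1,11.5
9,healthy,M2,19.5,14.2,12.6
9,healthy,M3,19.0,13.5,11.0
10,healthy,M1,19.8,14.4,12.2
10,healthy,M2,19.0,14.0,12.9
10,healthy,M3,19.8,14.3,12.8
11,addison,M1,9.6,7.7,7.2
12,addison,M1,10.7,8.0,7.1
13,addison,M1,11.1,9.0,7.1
14,addison,M1,10.8,8.8,7.4
15,addison,M1,8.8,8.7,7.3
"""


def relaxometry_table() -> pd.DataFrame:
    """Long-format relaxometry measurements (one row per subject x muscle)."""
    return pd.read_csv(io.StringIO(_RELAXOMETRY_CSV))


def tsc_table() -> pd.DataFrame:
    """Long-format TSC records: subject, group, muscle, session, tsc."""
    wide = pd.read_csv(io.StringIO(_TSC_CSV))
    long = wide.melt(id_vars=["subject", "group", "session"],
                     value_vars=list(MUSCLES), var_name="muscle",
                     value_name="tsc")
    return long.sort_values(["subject", "session", "muscle"]).reset_index(drop=True)


def write_fixture_csvs(out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    relaxometry_table().to_csv(out / "relaxometry_measurements.csv", index=False)
    tsc_table().to_csv(out / "tsc_measurements.csv", index=False)
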