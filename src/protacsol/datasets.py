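"""The published 21-degrader thermodynamic-solubility benchmark.

A panel of 21 commercial PROTACs measured by shake-flask HPLC-UV at pH 7 /
25 degC. Five compounds (ACBI1, cisACBI1, ARV-825, Mcl1 degrader-1,
MD-224) fell below the quantification limit: they are censored ("ND"),
classified low, and excluded from every regression, leaving 16
quantitative records. log S values (mol/L) are included where the source
reports them compound-by-compound; panel members without an individually
reported name or value carry synthetic placeholder entries (ids
``DEG-*``) so the panel structure — 21 compounds, 5 censored — is intact.

Building-block measurements cover the three published pair comparisons
(warhead, linker and E3-ligand swaps). JQ1 carboxylic acid exceeded the
assay ceiling and is censored *above* log S = -2.6.
"""

from __future__ import annotations

from .datatypes import CompoundRecord, Dataset, GskClass, Role, SolubilityMeasurement
from .models import LogS, Moiety
from .solubility import gsk_class

# (id, log S mol/L or None, censored-below-LOQ)
_PROTAC_PANEL: list[tuple[str, float | None, bool]] = [
    ("MZ1", -4.42, False),
    ("MZP-54", -6.29, False),
    ("dBET57", -4.52, False),
    ("ZXH-3-26", -5.53, False),
    ("BI-3663", -5.16, False),
    ("BI-0319", -5.58, False),
    ("BI-4206", -6.24, False),
    ("BSJ-03-123", None, False),
    ("CM11", None, False),
    ("CMP98", None, False),
    ("dBRD9", None, False),
    ("VZ185", None, False),
    # quantitative panel members without individually reported values
    ("DEG-13", None, False),
    ("DEG-14", None, False),
    ("DEG-15", None, False),
    ("DEG-16", None, False),
    # below the quantification limit ("ND") -> censored, low class
    ("ACBI1", None, True),
    ("cisACBI1", None, True),
    ("ARV-825", None, True),
    ("Mcl1 degrader-1", None, True),
    ("MD-224", None, True),
]

#: building-block log S (mol/L); JQ1 acid is censored above the assay ceiling
BUILDING_BLOCK_LOG_S: dict[str, LogS] = {
    "JQ1 carboxylic acid": LogS(-2.6, censor="above"),
    "I-BET726": LogS(-4.42),
    "pomalidomide": LogS(-4.44),
    "S,R,S-AHPC HCl": LogS(-2.68),
    "S,S,S-AHPC 2HCl": LogS(-2.69),
}

#: the three published pair comparisons: (protac A, protac B, varied moiety,
#: block A, block B); linker blocks were not measured -> None
BENCHMARK_PAIRS: list[tuple[str, str, Moiety, str | None, str | None]] = [
    ("MZ1", "MZP-54", Moiety.WARHEAD, "JQ1 carboxylic acid", "I-BET726"),
    ("dBET57", "ZXH-3-26", Moiety.LINKER, None, None),
    ("BI-3663", "BI-0319", Moiety.E3_LIGAND, "pomalidomide", "S,R,S-AHPC HCl"),
]


def load_protac_benchmark() -> Dataset:
    """The 21-compound panel as a Dataset (solubility layer only)."""
    ds = Dataset(metadata={"panel": "21 commercial PROTACs, shake-flask pH 7 / 25 degC"})
    for cid, log_s, censored in _PROTAC_PANEL:
        ds.compounds.append(CompoundRecord(id=cid, name=cid, role=Role.PROTAC))
        if censored:
            meas = SolubilityMeasurement(compound_id=cid, censored=True, gsk_class=GskClass.LOW)
        else:
            meas = SolubilityMeasurement(compound_id=cid, censored=False, log_s=log_s)
            if log_s is not None:
                meas.s_molar = 10.0 ** log_s
                meas.s_micromolar = meas.s_molar * 1e6
                meas.gsk_class = gsk_class(meas.s_micromolar)
        ds.solubility[cid] = meas
    return ds


def protac_log_s(dataset: Dataset | None = None) -> dict[str, LogS]:
    """Quantified panel log S values as interval-aware LogS objects."""
    ds = dataset or load_protac_benchmark()
    out: dict[str, LogS] = {}
    for cid, meas in ds.solubility.items():
        if meas.censored:
            continue
        if meas.log_s is not None:
            out[cid] = LogS(meas.log_s)
    return out
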