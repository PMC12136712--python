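"""Published worked-example data for the KPP105 phage, encoded
programmatically.

KPP105 is a lytic siphovirus isolated on *Klebsiella pneumoniae*
KBN K-1.  The host-range table below transcribes its spot-test and
efficiency-of-plating results against 15 ESBL-positive *K. pneumoniae*
strains and 9 other Gram-negative species; three *K. pneumoniae*
strains lyse in the spot test yet yield no plaques (EOP 0) and are
therefore counted resistant.  The stability figures give the reference
thermal-exposure endpoint used by the fold-reduction worked example.
"""

from __future__ import annotations

from .phenotype import AssayRow, AssayTable

#: Initial and post-exposure titers (log10 PFU/mL) at 50 degC for 60 min.
KPP105_LOG10_TITER_INITIAL = 8.5
KPP105_LOG10_TITER_50C_60MIN = 5.3

#: One-step growth-curve parameters of KPP105.
KPP105_LATENT_MIN = 20.0
KPP105_BURST_END_MIN = 60.0
KPP105_BURST_SIZE = 146.0

_KLEBSIELLA = "Klebsiella pneumoniae"

_HOST_RANGE_ROWS: list[tuple[str, str, str, float, bool]] = [
    # strain, species, spot, EOP %, is_host
    ("KBN K-1", _KLEBSIELLA, "+", 100.0, True),
    ("KBN K-2", _KLEBSIELLA, "+", 97.6, False),
    ("KBN P-1", _KLEBSIELLA, "+", 92.3, False),
    ("KBN B-1", _KLEBSIELLA, "+", 0.0, False),
    ("K01-KPN-13-134", _KLEBSIELLA, "+", 93.3, False),
    ("K01-KPN-13-149", _KLEBSIELLA, "+", 89.5, False),
    ("K07-KPN-13-002", _KLEBSIELLA, "+", 75.4, False),
    ("K14-KPN-13-016", _KLEBSIELLA, "+", 49.5, False),
    ("K16-KPN-13-008", _KLEBSIELLA, "+", 69.8, False),
    ("K16-KPN-13-022", _KLEBSIELLA, "+", 75.1, False),
    ("K20-KPN-12-057", _KLEBSIELLA, "+", 0.0, False),
    ("K20-KPN-12-067", _KLEBSIELLA, "+", 70.2, False),
    ("K21-KPN-12-013", _KLEBSIELLA, "+", 82.9, False),
    ("K22-KPN-13-007", _KLEBSIELLA, "+", 0.0, False),
    ("K22-KPN-13-013", _KLEBSIELLA, "+", 82.8, False),
    ("ATCC17978", "Acinetobacter baumannii", "-", 0.0, False),
    ("Clinical isolate 15-0628", "Citrobacter freundii", "-", 0.0, False),
    ("KCTC2949", "Cronobacter sakazakii", "-", 0.0, False),
    ("KCTC1039", "Escherichia coli", "-", 0.0, False),
    ("K01-ECO12-052", "ESBL(+) Escherichia coli", "-", 0.0, False),
    ("KCTC2566", "Proteus mirabilis", "-", 0.0, False),
    ("KCTC2004", "Pseudomonas aeruginosa", "-", 0.0, False),
    ("ATCC14028", "Salmonella Typhimurium", "-", 0.0, False),
    ("KCCM12021", "Salmonella Enteritidis", "-", 0.0, False),
]


def kpp105_host_range() -> AssayTable:
    """The KPP105 spot-test / EOP host-range assay as an AssayTable."""
    return AssayTable(
        rows=[
            AssayRow(
                strain_id=sid,
                species=sp,
                spot_result=spot,
                eop_percent=eop,
                is_host=host,
            )
            for sid, sp, spot, eop, host in _HOST_RANGE_ROWS
        ]
    )
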