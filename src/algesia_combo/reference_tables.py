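"""Published group-level summaries from a rat CCI combination study.

A low, sub-effective dose of amitriptyline (3 mg/kg i.p.) was combined with
three doses (25/50/100 mg/kg) of an aqueous or an ethanolic saffron
(*Crocus sativus*) stigma extract for 7 days after sciatic chronic
constriction injury.  The study reported, per combination and assay
statistic (mechanical raw AUC, cold-allodynia PI, thermal %MPE):

* the two mono-therapy means +/- SEM,
* the observed combination mean +/- SEM,
* the "expected" additive mean +/- SEM,
* whether the observed-vs-expected t-test was significant, and
* the printed interaction label.

Only the group summaries were published (no per-animal data), so these
cells serve as reference inputs for checking the additive-expectation
arithmetic and the classification rule, not as a fittable dataset.  Two
thermal expected-effect cells are internally inconsistent — the printed
expected mean does not equal the sum of the printed component means — and
are flagged ``consistent=False``.  n = 6 animals per arm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceCell", "REFERENCE_CELLS", "consistent_cells", "N_PER_ARM"]

N_PER_ARM = 6

MECH = "raw_auc"
COLD = "percent_inhibition"
HEAT = "percent_mpe"


@dataclass(frozen=True)
class ReferenceCell:
    """One combination x statistic cell of the published summary tables."""

    combo: str
    statistic: str
    mono_a: tuple[float, float]  # (mean, sem) of amitriptyline 3 mg/kg
    mono_b: tuple[float, float]  # (mean, sem) of the extract dose
    observed: tuple[float, float]
    expected: tuple[float, float]  # as printed
    significant: bool  # observed-vs-expected t-test < 0.05 as reported
    printed_label: str

    @property
    def consistent(self) -> bool:
        """Printed expected mean equals the component sum at print precision."""
        return (
            round(self.mono_a[0] + self.mono_b[0], 1) == round(self.expected[0], 1)
        )


_AMI3 = {MECH: (53.1, 5.0), COLD: (9.8, 5.2), HEAT: (7.3, 2.2)}


def _cells(combo, stat_rows):
    out = []
    for stat, mono_b, observed, expected, sig, label in stat_rows:
        out.append(
            ReferenceCell(
                combo=combo,
                statistic=stat,
                mono_a=_AMI3[stat],
                mono_b=mono_b,
                observed=observed,
                expected=expected,
                significant=sig,
                printed_label=label,
            )
        )
    return out


REFERENCE_CELLS: tuple[ReferenceCell, ...] = tuple(
    _cells(
        "Ami 3+Aq 25",
        [
            (MECH, (51.2, 5.2), (57.0, 5.5), (104.3, 3.43), False, "sub_additive"),
            (COLD, (3.0, 2.9), (1.6, 3.6), (12.8, 3.16), False, "sub_additive"),
            (HEAT, (0.9, 1.5), (4.3, 1.7), (8.2, 1.8), False, "sub_additive"),
        ],
    )
    + _cells(
        "Ami 3+Aq 50",
        [
            (MECH, (52.0, 7.2), (107.0, 23.0), (105.1, 3.9), False, "sub_additive"),
            (COLD, (12.0, 4.6), (46.0, 8.1), (21.8, 3.08), True, "potentiated"),
            (HEAT, (39.5, 2.5), (58.4, 11.2), (46.8, 3.07), True, "potentiated"),
        ],
    )
    + _cells(
        "Ami 3+Aq 100",
        [
            (MECH, (66.0, 9.7), (129.1, 13.0), (119.1, 5.6), True, "potentiated"),
            (COLD, (29.0, 3.5), (51.0, 4.03), (38.8, 3.4), True, "potentiated"),
            # expected cell inconsistent: components sum to 64.4, printed 67.8
            (HEAT, (57.1, 8.2), (74.7, 10.9), (67.8, 5.8), True, "potentiated"),
        ],
    )
    + _cells(
        "Ami 3+Eth 25",
        [
            (MECH, (52.4, 5.4), (62.1, 3.5), (105.5, 7.1), False, "sub_additive"),
            (COLD, (3.0, 4.5), (3.3, 3.5), (12.8, 3.51), False, "sub_additive"),
            (HEAT, (0.4, 1.3), (2.87, 0.02), (7.7, 1.8), False, "sub_additive"),
        ],
    )
    + _cells(
        "Ami 3+Eth 50",
        [
            (MECH, (58.5, 5.8), (70.3, 5.2), (111.6, 6.1), False, "sub_additive"),
            (COLD, (24.0, 4.8), (36.0, 4.5), (33.8, 4.4), True, "potentiated"),
            (HEAT, (28.3, 4.0), (56.0, 9.7), (35.6, 2.2), True, "potentiated"),
        ],
    )
    + _cells(
        "Ami 3+Eth 100",
        [
            (MECH, (70.0, 11.0), (116.9, 7.4), (123.1, 12.4), False, "sub_additive"),
            (COLD, (39.5, 4.4), (60.9, 5.2), (49.3, 4.8), True, "potentiated"),
            # expected cell inconsistent: components sum to 58.8, printed 62.8
            (HEAT, (51.5, 6.03), (65.2, 10.2), (62.8, 4.6), True, "potentiated"),
        ],
    )
)


def consistent_cells() -> tuple[ReferenceCell, ...]:
    """Cells whose printed expected mean equals the component sum."""
    return tuple(c for c in REFERENCE_CELLS if c.consistent)
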