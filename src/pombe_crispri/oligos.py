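"""Cloning oligos for Golden-Gate insertion of a spacer into the sgRNA gene.

The two synthesized oligos anneal into a short duplex whose 4-nt 5' overhangs
(CACC on the top strand, AAAC on the bottom) are complementary to the ends of
the BbsI-cut expression vector:

    5'-CACC NNNNNNNNNNNNNNNNNNNN      -3'   (top, 5'->3')
    3'-     NNNNNNNNNNNNNNNNNNNN CAAA -5'   (bottom; 5'->3' it reads AAAC + revcomp(spacer))

The annealing program denatures at 95 degC for 2 min, cools at -2 degC/min to
the spacer Tm, holds 5 min, then cools at -2 degC/min to 25 degC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from pombe_crispri.genome import AlphabetError, reverse_complement

TOP_OVERHANG_DEFAULT = "CACC"
BOTTOM_OVERHANG_DEFAULT = "AAAC"

#: Static protocol notes emitted alongside oligo reports (not computed).
PROTOCOL_NOTES = (
    "Oligos: standard desalting grade, 20 uM each in annealing buffer "
    "(10 mM Tris-HCl pH 8.0, 50 mM NaCl, 1 mM EDTA). "
    "Ligation: 2.0 pmol annealed insert + 0.03 pmol BbsI-cut vector."
)


@dataclass(frozen=True)
class ScheduleStep:
    description: str
    temperature_c: float | tuple[float, float]  # single temp or (from, to)
    minutes: float
    ramp_c_per_min: float | None = None


@dataclass(frozen=True)
class OligoPair:
    """The two annealing oligos (5'->3') plus spacer Tm and thermal program."""

    top: str
    bottom: str
    tm_c: float
    schedule: tuple[ScheduleStep, ...]


def _check_spacer(protospacer: str) -> None:
    bad = set(protospacer) - set("ACGT")
    if bad:
        raise AlphabetError(
            f"protospacer must be over A/C/G/T (no N): invalid {sorted(bad)}"
        )


def melting_temperature(protospacer: str, method: str = "wallace") -> float:
    """Spacer melting temperature in degC.

    Default is the Wallace rule, 2*(A+T) + 4*(G+C), the standard quick rule
    for short oligos. method="nearest_neighbor" switches to a thermodynamic
    nearest-neighbor estimate.
    """
    if len(protospacer) == 0:
        raise ValueError("empty protospacer")
    _check_spacer(protospacer)
    if method == "wallace":
        at = protospacer.count("A") + protospacer.count("T")
        gc = protospacer.count("G") + protospacer.count("C")
        return 2.0 * at + 4.0 * gc
    if method == "nearest_neighbor":
        return float(_mt.Tm_NN(protospacer))
    raise ValueError(f"unknown Tm method {method!r}")


def annealing_schedule(tm_c: float, ramp_c_per_min: float = 2.0) -> tuple[ScheduleStep, ...]:
    """Thermal-cycler program for annealing the two oligos.

    Steps: denature 95 degC 2 min; ramp to tm_c at -ramp degC/min; hold tm_c
    5 min; ramp to 25 degC at -ramp degC/min. Zero-duration ramps at the
    boundaries are retained as no-op steps. tm_c must lie in [25, 95].
    """
    if not (25.0 <= tm_c <= 95.0):
        raise ValueError(f"tm_c must be within [25, 95] degC, got {tm_c}")
    return (
        ScheduleStep("denature", 95.0, 2.0),
        ScheduleStep("ramp to Tm", (95.0, tm_c), (95.0 - tm_c) / ramp_c_per_min,
                     ramp_c_per_min=-ramp_c_per_min),
        ScheduleStep("hold at Tm", tm_c, 5.0),
        ScheduleStep("ramp to 25", (tm_c, 25.0), (tm_c - 25.0) / ramp_c_per_min,
                     ramp_c_per_min=-ramp_c_per_min),
    )


def make_oligo_pair(
    protospacer: str,
    top_overhang: str = TOP_OVERHANG_DEFAULT,
    bottom_overhang: str = BOTTOM_OVERHANG_DEFAULT,
    tm_method: str = "wallace",
) -> OligoPair:
    """Build the annealing oligo pair for one targeting sequence.

    top = top_overhang + protospacer; bottom = bottom_overhang +
    reverse_complement(protospacer). With the default CACC/AAAC overhangs the
    annealed duplex presents the 5' extensions complementary to a BbsI-cut
    vector. Spacer length must be 18-25 (a warning is logged when != 20,
    since the efficacy rules assume 20).
    """
    if not (18 <= len(protospacer) <= 25):
        raise ValueError(
            f"protospacer length must be 18-25, got {len(protospacer)}"
        )
    _check_spacer(protospacer)
    if len(protospacer) != 20:
        logging.getLogger(__name__).warning(
            "protospacer length %d != 20 nt", len(protospacer)
        )
    tm = melting_temperature(protospacer, method=tm_method)
    return OligoPair(
        top=top_overhang + protospacer,
        bottom=bottom_overhang + reverse_complement(protospacer),
        tm_c=tm,
        schedule=annealing_schedule(tm),
    )


def schedule_text(schedule: Sequence[ScheduleStep]) -> str:
    """Human-readable rendering of a thermal program."""
    lines = []
    for step in schedule:
        if isinstance(step.temperature_c, tuple):
            t0, t1 = step.temperature_c
            lines.append(
                f"{step.description}: {t0:g} -> {t1:g} degC at "
                f"{step.ramp_c_per_min:g} degC/min ({step.minutes:g} min)"
            )
        else:
            lines.append(
                f"{step.description}: {step.temperature_c:g} degC for {step.minutes:g} min"
            )
    return "\n".join(lines)


def oligos_to_tsv(pairs: dict[str, OligoPair]) -> str:
    """TSV report: guide id, top oligo, bottom oligo, Tm."""
    lines = ["guide_id\ttop_oligo\tbottom_oligo\ttm_c"]
    for guide_id, pair in pairs.items():
        lines.append(f"{guide_id}\t{pair.top}\t{pair.bottom}\t{pair.tm_c:g}")
    return "\n".join(lines) + "\n"
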