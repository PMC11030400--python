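"""Default QC analyte panels and expected isotope envelopes.

The monitoring scheme rests on three exogenous standards:

* system-suitability mix — a tryptic BSA digest carrier plus the 15 heavy
  retention-time-calibration (PRTC) peptides, injected as a standalone run
  before/during/after experiments (17 monitored precursors);
* protein internal QC — yeast enolase 1 (ENO), spiked into every sample before
  digestion, so its peptides report on the whole preparation;
* peptide internal QC — the same PRTC peptides, spiked immediately before
  injection, so they report on LC-MS function only.

Sequences are the standards' actual tryptic/synthetic peptides. Analyte ids
are "SEQUENCE/charge".
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .isotope import HeavyLabel, isotope_distribution, peptide_composition

# The 15 synthetic heavy PRTC peptides.
PRTC_SEQUENCES = (
    "SSAAPPPPPR",
    "GISNEGQNASIK",
    "HVLTSIGEK",
    "DIPVPKPK",
    "IGDYAGIK",
    "TASEFDSAIAQDK",
    "SAAGAFGPELSR",
    "ELGQSGVDTYLQTK",
    "GLILVGGYGTR",
    "GILFVGSGVSGGEEGAR",
    "SFANQPLEVVYSK",
    "LTILEELR",
    "NGFILDGFPR",
    "ELASGLSFPVGFK",
    "LSSEAPALFQFDLK",
)

# BSA tryptic peptides monitored alongside PRTC in the suitability mix.
BSA_SEQUENCES = ("LVNELTEFAK", "YLYEIAR")

# Yeast enolase 1 tryptic peptides used as the protein internal QC.
ENO_SEQUENCES = (
    "VNQIGTLSESIK",
    "AADALLLK",
    "AVDDFLISLDGTANK",
    "GNPTVEVELTTEK",
    "NVNDVIAPAFVK",
)

SUITABILITY_SEQUENCES = BSA_SEQUENCES + PRTC_SEQUENCES  # 17 peptides

_HEAVY = frozenset(PRTC_SEQUENCES)


def make_analyte_id(sequence: str, charge: int) -> str:
    return f"{sequence}/{charge}"


def split_analyte_id(analyte_id: str) -> tuple[str, int]:
    seq, _, z = analyte_id.partition("/")
    return seq, int(z) if z else 2


def is_heavy(sequence: str) -> bool:
    """PRTC peptides are heavy-labeled; carrier and spike proteins are not."""
    return sequence in _HEAVY


@lru_cache(maxsize=4096)
def expected_envelope(analyte_id: str, n_peaks: int = 3) -> np.ndarray:
    """Theoretical M0..M+k envelope for an analyte id, heavy label inferred."""
    seq, _ = split_analyte_id(analyte_id)
    label = HeavyLabel.K8R10 if is_heavy(seq) else HeavyLabel.NONE
    comp = peptide_composition(seq, heavy_label=label)
    return isotope_distribution(comp, n_peaks).as_array()
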