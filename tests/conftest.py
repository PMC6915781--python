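import logging

import pytest

from autocsc.io import Modification, PeptideObservation, ProteinRecord, SampleDesign
from autocsc.sites import Proteome


@pytest.fixture
def tiny_proteome() -> Proteome:
    """Three proteins with hand-placed sequons (1-based N positions noted)."""
    return Proteome(
        [
            # NGS at 2 (NXS), NKT at 7 (NXT)
            ProteinRecord("P1", "ANGSKANKTAAR"),
            # same NGSIK peptide embedded at offset 3
            ProteinRecord("P2", "MKNGSIKLLR"),
            # sequon-free
            ProteinRecord("P3", "MKAAAGGLLR"),
        ]
    )


@pytest.fixture
def design_2x2() -> SampleDesign:
    return SampleDesign.from_rows(
        [
            ("r1", "A", "b1", "t1"),
            ("r2", "A", "b1", "t2"),
            ("r3", "A", "b2", "t1"),
            ("r4", "B", "b1", "t1"),
            ("r5", "B", "b2", "t1"),
        ]
    )


def make_obs(
    peptide: str,
    deamid_at: list[int] | None = None,
    accessions: list[str] | None = None,
    q_value: float | None = 0.001,
    intensities: dict[str, float] | None = None,
) -> PeptideObservation:
    return PeptideObservation(
        peptide_sequence=peptide,
        modifications=[
            Modification(position=p, kind="Deamidated (N)") for p in (deamid_at or [])
        ],
        protein_accessions=accessions or ["P1"],
        q_value=q_value,
        intensities=intensities or {},
    )


@pytest.fixture
def caplog_warnings(caplog):
    caplog.set_level(logging.WARNING, logger="autocsc")
    return caplog
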