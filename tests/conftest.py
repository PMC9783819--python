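"""Shared fixtures: hypothesis profile, small chronograms, a tiny mzML writer."""

from __future__ import annotations

import base64

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import chronovoc as cv

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20221231)


@pytest.fixture
def small_config():
    """A short, cheap fungus configuration for structural tests."""
    return cv.default_config(
        "fungus",
        seed=7,
        duration_days=4,
        emission_onset_day=2.0,
        emission_peak_day=3.0,
        emission_offset_day=4.0,
    )


def _b64(arr) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def make_mzml(
    spectra: list[dict],
) -> str:
    """Render a minimal centroided mzML document.

    Each spectrum dict: ``mz``, ``intensity``, ``rt`` (value), optional
    ``unit`` (default minute), ``profile`` and ``with_rt`` flags.
    """
    chunks = []
    for idx, s in enumerate(spectra):
        mode = (
            '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum"/>'
            if s.get("profile")
            else '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
        )
        rt = ""
        if s.get("with_rt", True):
            unit = s.get("unit", "minute")
            rt = (
                '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
                f'value="{s["rt"]}" unitName="{unit}"/>'
            )
        chunks.append(
            f'<spectrum index="{idx}" id="scan={idx + 1}" '
            f'defaultArrayLength="{len(s["mz"])}">{mode}'
            f"<scanList count=\"1\"><scan>{rt}</scan></scanList>"
            '<binaryDataArrayList count="2">'
            '<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>'
            f"<binary>{_b64(s['mz'])}</binary></binaryDataArray>"
            '<binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>'
            f"<binary>{_b64(s['intensity'])}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        f'<run id="run1"><spectrumList count="{len(spectra)}">'
        + "".join(chunks)
        + "</spectrumList></run></mzML>"
    )


@pytest.fixture
def mzml_writer(tmp_path):
    def write(name: str, spectra: list[dict]) -> str:
        path = tmp_path / name
        path.write_text(make_mzml(spectra), encoding="utf-8")
        return str(path)

    return write
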