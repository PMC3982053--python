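"""Atlas label lists used to define graph nodes.

The whole-brain parcellation is the 90-region AAL cerebral atlas (cortex plus
subcortical gray matter, cerebellum excluded), in its conventional 1-based
ordering with left/right hemispheres interleaved.  The "cognitive circuit" is
a 60-label subset covering prefrontal, cingulate, medial-temporal, occipital,
parietal and basal-ganglia regions; it is shipped as an editable stand-in
configuration file, not as the output of any meta-analytic procedure.
"""

from __future__ import annotations

from importlib import resources

__all__ = ["aal90_labels", "cognitive_circuit_labels", "load_label_file"]


def _read_packaged(name: str) -> list[str]:
    text = resources.files("signet.data").joinpath(name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def aal90_labels() -> list[str]:
    """Return the 90 AAL region labels in atlas order."""
    return _read_packaged("aal90_labels.txt")


def cognitive_circuit_labels() -> list[str]:
    """Return the packaged 60-label cognitive-circuitry subset (atlas order)."""
    return _read_packaged("cognitive_circuit_60.txt")


def load_label_file(path: str) -> list[str]:
    """Read a user-supplied label list (one label per line, blanks ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
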