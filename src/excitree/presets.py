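"""Simulation presets.

``FULL`` reproduces the study protocol (10**6 steps, five repetitions per
condition); ``SCALED`` is a cheaper preset (10**5 steps, three repetitions)
for routine testing and quick sweeps.  ``PROFILE`` is the benchmark-neurite
protocol (10**5 steps, ten trials).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Preset:
    t_steps: int
    n_reps: int
    name: str = ""


FULL = Preset(t_steps=1_000_000, n_reps=5, name="full")
SCALED = Preset(t_steps=100_000, n_reps=3, name="scaled")
PROFILE = Preset(t_steps=100_000, n_reps=10, name="profile")

PRESETS = {p.name: p for p in (FULL, SCALED, PROFILE)}
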