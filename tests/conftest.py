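"""Shared test configuration.

Hypothesis runs derandomized so every invocation explores the identical,
reproducible example sequence; deadlines are disabled because the first call
into a numba-compiled kernel pays a one-off compilation cost.
"""

from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
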