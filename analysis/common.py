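"""Shared configuration for the numbered analysis scripts."""

from pathlib import Path

SEED = 1
N_UNIONS = 64
RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)
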