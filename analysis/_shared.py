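"""Shared plumbing for the numbered analysis drivers: locate (or create) the
synthetic fixture bundle and load it as analysis inputs."""

from __future__ import annotations

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
FIXTURE = RESULTS / "fixture"
SEED = 1


def fixture_bundle():
    """The in-memory bundle matching results/fixture (regenerates the files
    if they are missing; same seed, so outputs are reproducible)."""
    from hlagdiv.simulate import simulate_structured_locus, write_fixture_bundle

    bundle = simulate_structured_locus(seed=SEED)
    if not (FIXTURE / "checksums.json").exists():
        FIXTURE.parent.mkdir(parents=True, exist_ok=True)
        write_fixture_bundle(bundle, FIXTURE, overwrite=True)
    return bundle


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
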