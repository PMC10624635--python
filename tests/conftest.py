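"""Shared synthetic fixtures: strand->P-loop->helix backbones with ground truth."""

import pytest

from ploopkit.fixtures import (
    ORIENTATION_FAIL_PRE_TORSION,
    FixtureSpec,
    make_motif_fixture,
)


@pytest.fixture
def motif_model():
    """Default positive fixture (confirmed Walker-A hit) plus its truth."""
    return make_motif_fixture(FixtureSpec(seed=7))


@pytest.fixture
def motif_panel():
    """Positive/negative fixture panel with per-structure expectations.

    Returns a list of (model, expected_confirmed_start_or_None, failure_mode)
    tuples: 20 fully positive fixtures and 21 negatives split across
    sequence-only, torsion-only and orientation-only failures.
    """
    panel = []
    for seed in range(20):
        model, truth = make_motif_fixture(FixtureSpec(seed=seed))
        panel.append((model, truth.motif_starts_auth[0], "positive"))
    for seed in range(7):
        # right torsions, no Walker-A sequence: filler sequence over the
        # motif torsion pattern
        torsions = [(-120.0, 130.0, 180.0)] * 6
        from ploopkit.fixtures import ABEGO_REPRESENTATIVE

        loop = [ABEGO_REPRESENTATIVE[c] for c in "EBBGAGAA"]
        helix = [(-57.0, -47.0, 180.0)] * 8
        spec = FixtureSpec(
            segments=(
                ("explicit", "AVLIED", tuple(torsions)),
                ("explicit", "AVLIEDNQ", tuple(loop)),
                ("explicit", "MNQRFMAV", tuple(helix)),
            ),
            seed=100 + seed,
        )
        model, _ = make_motif_fixture(spec)
        panel.append((model, None, "sequence"))
    for seed in range(7):
        model, _ = make_motif_fixture(
            FixtureSpec(
                segments=(("strand", 6), ("motif", "GPPGAGKS", "AAAAAAAA"), ("helix", 8)),
                seed=200 + seed,
            )
        )
        panel.append((model, None, "torsion"))
    for seed in range(7):
        model, _ = make_motif_fixture(
            FixtureSpec(seed=300 + seed, pre_loop_override=ORIENTATION_FAIL_PRE_TORSION)
        )
        panel.append((model, None, "orientation"))
    return panel
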