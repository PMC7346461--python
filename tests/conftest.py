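import numpy as np
import pytest

from snakedent import Tooth, ToothRow, parse_newick, sim_yule_tree


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule20():
    return sim_yule_tree(20, seed=421)


def make_tooth_row(
    lengths,
    species="sp_test",
    positions=None,
    missing=(),
    grooved=(),
    groove_widths=None,
    cranium=30.0,
    maxilla=10.0,
):
    """Build a ToothRow from a length list; ``missing`` positions become
    socket-only records (their length entry is ignored)."""
    positions = positions or list(range(1, len(lengths) + 1))
    teeth = []
    for pos, length in zip(positions, lengths):
        if pos in missing:
            teeth.append(Tooth(position=pos, present=False))
        else:
            kw = {}
            if pos in grooved:
                gw = groove_widths or (0.1, 0.12, 0.14, 0.12, 0.12)
                kw = dict(
                    grooved=True,
                    groove_length_mm=0.5 * length,
                    groove_width_mm=tuple(gw),
                )
            teeth.append(Tooth(position=pos, length_mm=float(length), **kw))
    return ToothRow(
        species=species,
        specimen_id="s1",
        cranium_length_mm=cranium,
        maxilla_length_mm=maxilla,
        teeth=teeth,
    )
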