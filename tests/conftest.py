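import pytest

import burstwkb as bw


@pytest.fixture(scope="session")
def pos_fb_fig1():
    """Positive feedback, fixed burst size 1 (a0=2, a1=10, s_max=20)."""
    return bw.load_preset("pos_fb_fig1").model(0.1)


@pytest.fixture(scope="session")
def neg_fb_fig3():
    """Negative feedback, fixed burst size 4 (a0=2.5, a1=0.5): monostable."""
    return bw.load_preset("neg_fb_fig3").model(0.1)


@pytest.fixture(scope="session")
def pos_fb_fig4():
    """Positive feedback, fixed burst size 4 (a0=0.5, a1=2.5): bistable."""
    return bw.load_preset("pos_fb_fig4").model(0.05)


@pytest.fixture(scope="session")
def fig3_fps(neg_fb_fig3):
    return bw.find_fixed_points(neg_fb_fig3)


@pytest.fixture(scope="session")
def fig4_fps(pos_fb_fig4):
    return bw.find_fixed_points(pos_fb_fig4)


@pytest.fixture(scope="session")
def fig3_branch(neg_fb_fig3, fig3_fps):
    branch = bw.trace_branch(neg_fb_fig3, fig3_fps)
    bw.potential(branch)
    bw.prefactor(neg_fb_fig3, branch)
    return branch


@pytest.fixture(scope="session")
def fig4_branch(pos_fb_fig4, fig4_fps):
    branch = bw.trace_branch(pos_fb_fig4, fig4_fps)
    bw.potential(branch)
    bw.prefactor(pos_fb_fig4, branch)
    return branch
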