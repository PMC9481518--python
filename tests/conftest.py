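import pytest

from hybnum.netcore import PhyloNetwork, PloidyProfile


@pytest.fixture
def bead():
    """Smallest valid beaded network: root, two parallel arcs to a hybrid,
    arc to a leaf x1 (path count 2)."""
    net = PhyloNetwork()
    root = net.new_vertex()
    hyb = net.new_vertex()
    leaf = net.new_vertex(label="x1")
    net.add_arc(root, hyb)
    net.add_arc(root, hyb)
    net.add_arc(hyb, leaf)
    return net


@pytest.fixture
def cherry_tree():
    """Two-leaf tree (counts 1, 1)."""
    net = PhyloNetwork()
    root = net.new_vertex()
    for lab in ("x1", "x2"):
        leaf = net.new_vertex(label=lab)
        net.add_arc(root, leaf)
    return net


def profile(*mults, labels=None):
    return PloidyProfile.from_multiplicities(list(mults), labels)


def assert_consistent(net):
    """The two independent path-counting routes must agree, and the network
    must be a valid binary network whose counts respect the 2^h ceiling."""
    assert net.validate() == []
    counts = net.path_count_vector()
    assert dict(net.unfold_leaf_multiset()) == counts
    if net.is_binary():
        h = net.hybrid_number()
        assert all(c <= 2**h for c in counts.values())
    return counts
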