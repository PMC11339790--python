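"""Multi-scale extraction and the spatial-information-retained rearrangement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retiqa.backbone import PRESETS, ResidualBackbone, extract_multiscale
from retiqa.nn import Tensor, no_grad
from retiqa.sir import (SIRExtractor, chunk_concat, reassemble,
                        space_to_depth, spatial_split)

rng = np.random.default_rng(7)


# --- naive loop oracles --------------------------------------------------

def loop_split_concat(x, th, tw):
    """Explicit double-loop split + channel stack, row-major chunk order."""
    b, c, h, w = x.shape
    gh, gw = h // th, w // tw
    out = np.empty((b, gh * gw * c, th, tw), dtype=x.dtype)
    j = 0
    for m in range(gh):
        for n in range(gw):
            out[:, j * c:(j + 1) * c] = x[:, :, m * th:(m + 1) * th,
                                          n * tw:(n + 1) * tw]
            j += 1
    return out


class TestSplitConcat:
    def test_chunk_counts_are_side_invariant(self):
        # the /4, /8, /16 grids always hold 64, 16, 4 chunks of the /32 size
        for side in (64, 128, 512):
            t = side // 32
            for scale, k in zip((4, 8, 16), (64, 16, 4)):
                grid = spatial_split(np.zeros((1, 2, side // scale, side // scale),
                                              dtype=np.float32), t, t)
                assert len(grid) == k

    def test_single_chunk_identity(self):
        x = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        grid = spatial_split(x, 4, 4)
        assert len(grid) == 1
        np.testing.assert_array_equal(chunk_concat(grid), x)

    def test_reassemble_inverts_split_bitexactly(self):
        x = rng.normal(size=(2, 5, 12, 8)).astype(np.float32)
        np.testing.assert_array_equal(reassemble(spatial_split(x, 4, 4)), x)

    def test_concat_blocks_equal_tiles_by_coordinate_tagging(self):
        # map filled with its own (row*1000 + col) coordinates
        h = w = 8
        coords = (np.arange(h)[:, None] * 1000 + np.arange(w)[None, :])
        x = np.broadcast_to(coords, (1, 2, h, w)).astype(np.float32)
        out = chunk_concat(spatial_split(x, 4, 4))
        oracle = loop_split_concat(x, 4, 4)
        np.testing.assert_array_equal(out, oracle)
        # block 1 (chunk at row 0, col 1) holds columns 4..7 of rows 0..3
        np.testing.assert_array_equal(out[0, 2], coords[:4, 4:])

    def test_space_to_depth_equals_loop_oracle(self):
        x = rng.normal(size=(2, 3, 16, 16)).astype(np.float32)
        fused = space_to_depth(Tensor(x), 4, 4).data
        np.testing.assert_array_equal(fused, loop_split_concat(x, 4, 4))
        np.testing.assert_array_equal(fused, chunk_concat(spatial_split(x, 4, 4)))

    def test_element_multiset_conserved(self):
        x = rng.normal(size=(1, 16, 32, 32)).astype(np.float32)
        out = space_to_depth(Tensor(x), 8, 8).data
        assert out.size == x.size
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(x.ravel()))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.integers(1, 5), gh=st.integers(1, 4), gw=st.integers(1, 4),
           th=st.integers(1, 5), tw=st.integers(1, 5), seed=st.integers(0, 10))
    def test_split_concat_is_a_position_bijection(self, c, gh, gw, th, tw, seed):
        """For any grid geometry, split+concat neither drops nor duplicates
        elements and reassembly inverts the split exactly."""
        x = np.random.default_rng(seed).normal(
            size=(1, c, gh * th, gw * tw)).astype(np.float32)
        grid = spatial_split(x, th, tw)
        assert len(grid) == gh * gw
        stacked = chunk_concat(grid)
        assert stacked.shape == (1, gh * gw * c, th, tw)
        np.testing.assert_array_equal(np.sort(stacked.ravel()),
                                      np.sort(x.ravel()))
        np.testing.assert_array_equal(reassemble(grid), x)
        np.testing.assert_array_equal(space_to_depth(Tensor(x), th, tw).data,
                                      stacked)

    def test_non_divisible_raises(self):
        with pytest.raises(ValueError, match="not divisible"):
            spatial_split(np.zeros((1, 1, 10, 10), dtype=np.float32), 4, 4)

    def test_inconsistent_chunk_shapes_rejected(self):
        grid = spatial_split(np.zeros((1, 1, 8, 8), dtype=np.float32), 4, 4)
        grid.chunks[1] = grid.chunks[1][:, :, :2]
        with pytest.raises(ValueError, match="inconsistent"):
            chunk_concat(grid)


class TestBackboneContracts:
    def test_full_stage_channels(self):
        assert PRESETS["resnet50"].stage_channels == (256, 512, 1024, 2048)

    def test_reduced_backbone_shapes_and_batching(self):
        bb = ResidualBackbone("reduced", seed=0).eval()
        x = Tensor(rng.random((3, 3, 128, 128), dtype=np.float32))
        with no_grad():
            s = extract_multiscale(bb, x)
        ch = PRESETS["reduced"].stage_channels
        for i, (si, c, f) in enumerate(zip(s, ch, (4, 8, 16, 32))):
            assert si.shape == (3, c, 128 // f, 128 // f), f"stage {i+1}"

    def test_small_input_gives_4x4_stage4(self):
        bb = ResidualBackbone("reduced", seed=0).eval()
        with no_grad():
            s = bb(Tensor(np.zeros((1, 3, 128, 128), dtype=np.float32)))
        assert s[3].shape[2:] == (4, 4)

    def test_side_not_divisible_by_32_rejected(self):
        bb = ResidualBackbone("reduced", seed=0)
        with pytest.raises(ValueError, match="divisible by 32"):
            bb(Tensor(np.zeros((1, 3, 100, 100), dtype=np.float32)))


def naive_sir_forward(ext, x):
    """Loop-based reference for the full SIR pipeline (no fused rearrange)."""
    with no_grad():
        s = ext.backbone(Tensor(x))
        th, tw = s[3].shape[2], s[3].shape[3]
        feats = []
        for i in range(3):
            sp = ext.rescale(i + 1, s[i]).data
            stacked = loop_split_concat(sp, th, tw)
            feats.append(getattr(ext, f"project{i + 1}")(Tensor(stacked)).data)
        feats.append(ext.project4(s[3]).data)
    return np.concatenate(feats, axis=1)


class TestSIRExtractor:
    def test_feature_contract_reduced(self, reduced_extractor):
        x = Tensor(rng.random((2, 3, 128, 128), dtype=np.float32))
        with no_grad():
            f = reduced_extractor(x)
        assert f.shape == (2, 4 * 32, 4, 4)

    def test_equals_naive_loop_reference(self, reduced_extractor):
        x = rng.random((2, 3, 64, 64), dtype=np.float32)
        with no_grad():
            fast = reduced_extractor(Tensor(x)).data
        slow = naive_sir_forward(reduced_extractor, x)
        np.testing.assert_array_equal(fast, slow)

    def test_rescaled_activations_nonnegative(self, reduced_extractor):
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        with no_grad():
            s = reduced_extractor.backbone(x)
            for i in range(3):
                sp = reduced_extractor.rescale(i + 1, s[i])
                assert sp.data.min() >= 0
                assert sp.shape[2:] == s[i].shape[2:]

    def test_eval_mode_deterministic(self, reduced_extractor):
        x = Tensor(rng.random((1, 3, 64, 64), dtype=np.float32))
        with no_grad():
            a = reduced_extractor(x).data
            b = reduced_extractor(x).data
        np.testing.assert_array_equal(a, b)
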