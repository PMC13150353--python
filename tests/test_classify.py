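"""Cell-type assignment: marker contrast, colocalization, chain geometry."""

import numpy as np
import pytest

import cortexcount as cc
from cortexcount.classify import GeometryParams, is_vascular_by_geometry
from cortexcount.metrics import classification_scores, match_cells
from cortexcount.segment import SegmentedNucleus


def make_nucleus(i, center, aspect=1.0, axis=(0, 1.0, 0), marker_mean=1000.0,
                 background=(1000.0, 100.0)):
    c = np.asarray(center, dtype=float)
    return SegmentedNucleus(
        id=i, centroid_um=c, volume_um3=150.0,
        bbox_um=(tuple(c - 3), tuple(c + 3)),
        principal_axes_um=np.array([3.0 * aspect, 3.0, 3.0]),
        aspect_ratio=aspect,
        channel_means={"neuron_marker": marker_mean},
        channel_background={"neuron_marker": background},
        long_axis=np.asarray(axis, dtype=float) / np.linalg.norm(axis))


class TestIsNeuron:
    def test_contrast_threshold(self):
        pos, score = cc.is_neuron(make_nucleus(0, (10, 10, 10),
                                               marker_mean=1500.0))
        assert pos and score == pytest.approx(5.0)

    def test_zero_contrast_negative(self):
        pos, score = cc.is_neuron(make_nucleus(0, (10, 10, 10),
                                               marker_mean=1000.0))
        assert not pos and score == 0.0

    def test_missing_channel_is_error(self):
        nuc = make_nucleus(0, (10, 10, 10))
        nuc.channel_means = {}
        with pytest.raises(ValueError, match="neuron_marker"):
            cc.is_neuron(nuc)

    def test_rendered_neurons_positive_glia_negative(self, human_column):
        cells, nuclei = human_column["cells"], human_column["nuclei"]
        pairs, _ = match_cells(np.array([c.center_um for c in cells]),
                               np.array([n.centroid_um for n in nuclei]))
        hits = {"neuron": [], "glia": []}
        for i, j in pairs:
            cls = cells[i].cell_class
            if cls in hits:
                hits[cls].append(cc.is_neuron(nuclei[j])[0])
        assert np.mean(hits["neuron"]) >= 0.97
        assert np.mean(hits["glia"]) <= 0.03

    def test_raising_k_never_increases_neuron_count(self, human_column):
        nuclei = human_column["nuclei"]
        counts = [sum(cc.is_neuron(n, k=k)[0] for n in nuclei)
                  for k in (2.0, 4.0, 8.0, 16.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestVascularByMarker:
    def test_wall_cells_positive_distant_glia_negative(self, mouse_column):
        from cortexcount.classify import (vessel_distance_map,
                                          vessel_mask_from_stack)

        stack, cells = mouse_column["stack"], mouse_column["cells"]
        nuclei = mouse_column["nuclei"]
        vmask = vessel_mask_from_stack(stack)
        dmap = vessel_distance_map(vmask, stack.voxel_size_um)
        pairs, _ = match_cells(np.array([c.center_um for c in cells]),
                               np.array([n.centroid_um for n in nuclei]))
        vasc_hits, far_glia_hits = [], []
        for i, j in pairs:
            hit = cc.is_vascular_by_marker(nuclei[j], vmask, _dist_map=dmap)
            if cells[i].cell_class == "vascular":
                vasc_hits.append(hit)
            elif cells[i].cell_class == "glia":
                # only glia well away from every vessel are clean negatives
                (z0, y0, x0), (z1, y1, x1) = nuclei[j].bbox_voxels
                if dmap[z0:z1, y0:y1, x0:x1][nuclei[j].mask].min() > 15.0:
                    far_glia_hits.append(hit)
        assert np.mean(vasc_hits) >= 0.95
        assert far_glia_hits and not any(far_glia_hits)

    def test_marker_mode_requires_vessel_channel(self, human_column):
        with pytest.raises(ValueError, match="geometry"):
            cc.classify_all(human_column["nuclei"], human_column["stack"],
                            mode="marker")

    def test_empty_vessel_mask_all_negative(self):
        nuc = make_nucleus(0, (5, 5, 5))
        nuc.bbox_voxels = ((0, 0, 0), (3, 3, 3))
        nuc.mask = np.ones((3, 3, 3), dtype=bool)
        empty = np.zeros((10, 10, 10), dtype=bool)
        assert not cc.is_vascular_by_marker(nuc, empty,
                                            voxel_size_um=(1, 1, 1))


class TestVascularByGeometry:
    def test_straight_chain_of_elongated_nuclei_detected(self):
        nuclei = [make_nucleus(i, (25, 10 + 10 * i, 25), aspect=2.5)
                  for i in range(6)]
        flags = is_vascular_by_geometry(nuclei)
        assert flags.all()

    def test_isolated_round_nucleus_not_vascular(self):
        chain = [make_nucleus(i, (25, 10 + 10 * i, 25), aspect=2.5)
                 for i in range(4)]
        loner = make_nucleus(99, (100, 100, 100), aspect=1.1)
        flags = is_vascular_by_geometry(chain + [loner])
        assert flags[:4].all() and not flags[4]

    def test_chain_below_min_length_rejected(self):
        lone = [make_nucleus(0, (25, 10, 25), aspect=2.5)]
        assert not is_vascular_by_geometry(
            lone, GeometryParams(min_chain_len=2)).any()

    def test_degenerate_shapes_never_seed_chains(self):
        nuclei = [make_nucleus(i, (25, 10 + 10 * i, 25), aspect=3.0)
                  for i in range(4)]
        for n in nuclei:
            n.degenerate = True
        assert not is_vascular_by_geometry(nuclei).any()

    def test_misaligned_elongated_nuclei_do_not_link(self):
        # perpendicular long axes at chain spacing: axis test must fail
        nuclei = [
            make_nucleus(0, (25, 10, 25), aspect=2.5, axis=(0, 1, 0)),
            make_nucleus(1, (25, 20, 25), aspect=2.5, axis=(1, 0, 0)),
            make_nucleus(2, (25, 30, 25), aspect=2.5, axis=(0, 0, 1)),
        ]
        assert not is_vascular_by_geometry(nuclei).any()

    def test_recall_precision_on_human_stack(self, human_column):
        """On a rendered no-vessel-channel stack the chain detector finds
        vascular nuclei with recall and precision >= 0.85."""
        cells, nuclei = human_column["cells"], human_column["nuclei"]
        stack = human_column["stack"]
        classified = cc.classify_all(nuclei, stack, mode="geometry")
        ext = np.asarray(stack.extent_um)
        region = (np.full(3, 6.0), ext - 6.0)
        s = classification_scores(cells, classified, region)["per_class"]
        assert s["vascular"]["recall"] >= 0.85
        assert s["vascular"]["precision"] >= 0.85


class TestClassifyAll:
    def test_partition_and_conservation(self, mouse_column):
        nuclei = mouse_column["nuclei"]
        out = cc.classify_all(nuclei, mouse_column["stack"], mode="marker")
        assert len(out) == len(nuclei)
        counts = {"neuron": 0, "glia": 0, "vascular": 0}
        for c in out:
            counts[c.cell_class] += 1
        assert sum(counts.values()) == len(nuclei)

    def test_neuron_precedence_over_vascular(self, mouse_column):
        """Marker-positive nuclei are neurons even when vessel-adjacent."""
        stack = mouse_column["stack"]
        out = cc.classify_all(mouse_column["nuclei"], stack, mode="marker")
        from cortexcount.classify import (vessel_distance_map,
                                          vessel_mask_from_stack)

        dmap = vessel_distance_map(vessel_mask_from_stack(stack),
                                   stack.voxel_size_um)
        adjacent_neurons = 0
        for c in out:
            if c.cell_class != "neuron":
                continue
            (z0, y0, x0), (z1, y1, x1) = c.nucleus.bbox_voxels
            if dmap[z0:z1, y0:y1, x0:x1][c.nucleus.mask].min() <= 2.0:
                adjacent_neurons += 1
        assert adjacent_neurons > 0  # precedence actually exercised

    def test_modes_agree_on_vascular_calls(self, mouse_column):
        """Marker and geometry mode agree on >= 90% of vascular calls when
        both channels exist."""
        nuclei, stack = mouse_column["nuclei"], mouse_column["stack"]
        by_marker = cc.classify_all(nuclei, stack, mode="marker")
        by_geometry = cc.classify_all(nuclei, stack, mode="geometry")
        vascular_any = [
            (a.cell_class, b.cell_class)
            for a, b in zip(by_marker, by_geometry)
            if "vascular" in (a.cell_class, b.cell_class)
        ]
        agree = sum(a == b for a, b in vascular_any)
        assert vascular_any and agree / len(vascular_any) >= 0.9

    def test_evidence_consistency_enforced(self):
        nuc = make_nucleus(0, (5, 5, 5))
        with pytest.raises(ValueError):
            cc.ClassifiedCell(nucleus=nuc, cell_class="neuron",
                              evidence="geometry")

    def test_invalid_mode_rejected(self, human_column):
        with pytest.raises(ValueError, match="mode"):
            cc.classify_all(human_column["nuclei"], human_column["stack"],
                            mode="nope")
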