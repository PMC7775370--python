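import numpy as np
import pytest

from flapskit import chrom, imaging, synth


@pytest.fixture(scope="session")
def laminarin():
    return synth.SubstrateSpec(name="laminarin", parent_dp=100)


@pytest.fixture(scope="session")
def calib(laminarin):
    return synth.default_calibration(laminarin.parent_dp)


@pytest.fixture(scope="session")
def fine_bins(laminarin):
    return chrom.MWBinning.log_spaced(laminarin.parent_dp, 16)


@pytest.fixture(scope="session")
def detection_params():
    return imaging.DetectionParams()


def match_detections_to_truth(dapi_objs, truth):
    """Nearest-centroid assignment of detected DAPI objects to placed cells."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth[["row", "col"]].values)
    centroids = np.array([o.centroid for o in dapi_objs])
    dist, idx = tree.query(centroids)
    return dist, idx
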