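import numpy as np
import pytest

from cytotemplates.model import ClusterSummary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cluster(rng, p=3, n=50, scale=1.0, mean_spread=5.0):
    """A random valid Gaussian cluster summary."""
    mean = rng.normal(0.0, mean_spread, size=p)
    A = rng.normal(0.0, scale, size=(p, p))
    cov = A @ A.T + 0.1 * np.eye(p)
    return ClusterSummary(mean=mean, covariance=cov, size=n)


def brute_force_mec_cost(d: np.ndarray, lam: float) -> float:
    """Minimum mixed-edge-cover cost by exhaustive enumeration.

    Enumerates every subset of the ka*kb bipartite edges; the cost of a
    subset is the sum of its edge distances plus lambda per vertex left
    uncovered. This is the definition of the objective, evaluated without
    any optimization, so it is an independent oracle for the exact solver.
    """
    ka, kb = d.shape
    n_edges = ka * kb
    assert n_edges <= 20, "enumeration oracle limited to small instances"
    subsets = np.arange(2 ** n_edges, dtype=np.int64)
    member = ((subsets[:, None] >> np.arange(n_edges)) & 1).astype(bool)
    costs = member @ d.ravel()
    for i in range(ka):
        covered = member[:, i * kb : (i + 1) * kb].any(axis=1)
        costs += lam * (~covered)
    for j in range(kb):
        covered = member[:, j::kb].any(axis=1)
        costs += lam * (~covered)
    return float(costs.min())


def write_minimal_fcs(path, values, channel_names):
    """Write a minimal single-dataset FCS 3.1 list-mode float file.

    Test-only helper (the package itself does not write FCS); produces the
    simplest standard-conforming layout: 58-byte header, TEXT segment with
    '/' delimiter, float32 little-endian DATA.
    """
    values = np.asarray(values, dtype="<f4")
    n, p = values.shape
    data = values.tobytes()

    def text_for(data_start, data_end):
        fields = {
            "$DATATYPE": "F",
            "$MODE": "L",
            "$BYTEORD": "1,2,3,4",
            "$PAR": str(p),
            "$TOT": str(n),
            "$NEXTDATA": "0",
            "$BEGINDATA": str(data_start),
            "$ENDDATA": str(data_end),
        }
        for i, name in enumerate(channel_names, start=1):
            fields[f"$P{i}B"] = "32"
            fields[f"$P{i}N"] = name
            fields[f"$P{i}E"] = "0,0"
            fields[f"$P{i}R"] = "262144"
        body = "/" + "/".join(f"{k}/{v}" for k, v in fields.items()) + "/"
        return body.encode("ascii")

    text_start = 58
    # Iterate since BEGINDATA/ENDDATA digits feed back into the TEXT length
    data_start = data_end = 0
    for _ in range(5):
        text = text_for(data_start, data_end)
        new_start = text_start + len(text)
        new_end = new_start + len(data) - 1
        if (new_start, new_end) == (data_start, data_end):
            break
        data_start, data_end = new_start, new_end
    text = text_for(data_start, data_end)
    text_end = text_start + len(text) - 1

    header = b"FCS3.1    "
    header += f"{text_start:>8d}".encode()
    header += f"{text_end:>8d}".encode()
    header += f"{data_start:>8d}".encode()
    header += f"{data_end:>8d}".encode()
    header += f"{0:>8d}".encode() * 2  # no ANALYSIS segment
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header + text + data)
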