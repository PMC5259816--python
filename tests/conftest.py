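import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mutclass import BinaryMutationMatrix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_matrix() -> BinaryMutationMatrix:
    """5 genes × 4 samples worked example.

    Row sums 4,3,2,2,1; at similarity threshold 0.6 only genes 1 and 2
    (Jaccard 3/4) group together.
    """
    values = np.array(
        [
            [1, 1, 1, 1],
            [1, 1, 1, 0],
            [1, 1, 0, 0],
            [0, 0, 1, 1],
            [0, 0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return BinaryMutationMatrix(values, [f"g{i}" for i in range(1, 6)],
                                [f"s{j}" for j in range(1, 5)])


@pytest.fixture
def maf_file(tmp_path):
    """10-record MAF-like file: 3 genes × 4 samples, mixed Silent/Missense.

    Hand tabulation of non-Silent incidence:
        gene    S1 S2 S3 S4
        BRAF     0  1  1  0
        KRAS     1  0  0  1
        TP53     1  1  0  0
    (TP53/S3 and KRAS/S2 appear only as Silent records; TP53/S1 twice.)
    """
    records = [
        ("TP53", "S1", "Missense_Mutation"),
        ("TP53", "S1", "Nonsense_Mutation"),
        ("TP53", "S2", "Missense_Mutation"),
        ("TP53", "S3", "Silent"),
        ("KRAS", "S1", "Missense_Mutation"),
        ("KRAS", "S2", "Silent"),
        ("KRAS", "S4", "Missense_Mutation"),
        ("BRAF", "S2", "Splice_Site"),
        ("BRAF", "S3", "Missense_Mutation"),
        ("BRAF", "S3", "Silent"),
    ]
    path = tmp_path / "calls.maf.tsv"
    lines = ["Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification"]
    lines += ["\t".join(r) for r in records]
    path.write_text("\n".join(lines) + "\n")
    return path
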