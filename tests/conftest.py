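import pytest

from tsmr.summary_io import HarmonizedPair, SnpAssociation

TABLE1_TEXT = """\
SNP	Chr	EA	OA	Beta	SE	P	EAF
rs11057830	12	A	G	0.03	0.01	8.2e-9	0.15
rs2108622	19	T	C	0.03	0.01	1.4e-10	0.21
rs964184	11	G	C	0.04	0.01	7.8e-12	0.15
"""


@pytest.fixture
def instrument_file(tmp_path):
    """The 3-SNP alpha-tocopherol instrument table as a parseable file."""
    path = tmp_path / "instruments.tsv"
    path.write_text(TABLE1_TEXT)
    return path


def make_pairs(e_betas, d_betas, d_ses, se_e=0.01, rsids=None, eaf=0.25):
    """Build allele-aligned exposure/outcome pairs from raw effect arrays."""
    pairs = []
    for i, (e, d, sd) in enumerate(zip(e_betas, d_betas, d_ses)):
        rsid = rsids[i] if rsids else f"rs{i + 1:04d}"
        exposure = SnpAssociation(
            rsid=rsid, effect_allele="A", other_allele="G", beta=e, se=se_e, eaf=eaf
        )
        outcome = SnpAssociation(
            rsid=rsid, effect_allele="A", other_allele="G", beta=d, se=sd, eaf=eaf
        )
        pairs.append(
            HarmonizedPair(
                rsid=rsid,
                exposure=exposure,
                outcome=outcome,
                flip_applied=False,
                palindromic=False,
                resolution="direct",
            )
        )
    return pairs


@pytest.fixture
def pair_factory():
    return make_pairs
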