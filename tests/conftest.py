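import pytest

from cifaudit import curation as cur
from cifaudit.cif_io import extract_items, read_cif_text
from cifaudit.synthetic_corpus import build_default_spec, generate_corpus

MINIMAL_CIF = """\
data_test
_refine_ls_R_factor_gt 0.0460
_refine_ls_wR_factor_ref 0.1180
_refine_ls_goodness_of_fit_ref 1.045
_refine_ls_shift/su_max 0.001
_refine_diff_density_max 0.596
_refine_diff_density_min -0.481
_diffrn_reflns_theta_max 26.37
loop_
_diffrn_radiation_wavelength
0.71073
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_occupancy
C1 C 1
H1 H 1
N1 N 1
O1 O 1
"""


@pytest.fixture
def minimal_entry():
    return read_cif_text(MINIMAL_CIF)


@pytest.fixture(scope="session")
def small_spec():
    spec = build_default_spec(n=300, seed=7)
    # explicit, test-friendly quotas
    spec.quotas = {
        tag: {"missing": 12, "malformed": 0, "out_of_range": 0}
        for tag in cur.METRIC_TAGS
    }
    spec.quotas[cur.TAG_GOOF] = {"missing": 10, "malformed": 7, "out_of_range": 3}
    spec.quotas[cur.TAG_SHIFT] = {"missing": 9, "malformed": 5, "out_of_range": 2}
    return spec


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    """(files, ground_truth) for a 300-entry corpus with known quotas."""
    return generate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_audit(small_corpus):
    files, gt = small_corpus
    entries = [read_cif_text(text, name) for name, text in files]
    raw = [extract_items(e, cur.TAGS) for e in entries]
    sites = {e.identifier: e.atom_sites for e in entries}
    result, records = cur.audit_corpus(raw, atom_sites=sites)
    return entries, result, records, gt
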