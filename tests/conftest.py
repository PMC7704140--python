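import pytest

import herbbasket as hb


@pytest.fixture(scope="session")
def paper_table() -> hb.FormulaTable:
    return hb.builtin_paper_formulas()


@pytest.fixture(scope="session")
def by_rank_db(paper_table) -> hb.TransactionDB:
    return hb.to_transactions(paper_table, hb.Orientation.BY_RANK)


@pytest.fixture(scope="session")
def by_formula_db(paper_table) -> hb.TransactionDB:
    return hb.to_transactions(paper_table, hb.Orientation.BY_FORMULA)


@pytest.fixture(scope="session")
def paper_rules() -> list[hb.AssociationRule]:
    return hb.replicate_paper_rules()
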