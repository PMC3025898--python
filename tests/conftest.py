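import datetime as dt

import pandas as pd
import pytest

from rxpersist.catalog import default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def worked_example():
    """Index fill Jan 1 with refills Mar 15, May 1 and Jul 15, nothing after."""
    index = dt.date(2003, 1, 1)
    fills = [index, dt.date(2003, 3, 15), dt.date(2003, 5, 1),
             dt.date(2003, 7, 15)]
    return index, fills


def make_claims(day_products, patient_id="P1", origin=dt.date(2003, 6, 1),
                form="vial_syringe", route="injectable"):
    """Pharmacy-claims frame from (day_offset, product_name) pairs."""
    rows = []
    for item in day_products:
        offset, product = item[0], item[1]
        rows.append({
            "patient_id": patient_id,
            "fill_date": origin + dt.timedelta(days=int(offset)),
            "product_name": product,
            "quantity_ml": 10.0,
            "copay": 15.0,
            "form": item[2] if len(item) > 2 else form,
            "route": item[3] if len(item) > 3 else route,
        })
    return pd.DataFrame(rows)


@pytest.fixture
def claim_builder():
    return make_claims
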