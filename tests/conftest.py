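import random

import pytest

from entrez_agent.client import BlastRequest, EutilsRequest
from entrez_agent.prompts import ComponentStore


@pytest.fixture(scope="session")
def store() -> ComponentStore:
    return ComponentStore.load()


# Characters exercising percent-encoding in URL round-trips.
_VALUE_ALPHABET = (
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    " +&=?/:#%[]@!$'()*,;-._~éß漢"
)


def random_value(rng: random.Random, min_len: int = 1, max_len: int = 24) -> str:
    n = rng.randint(min_len, max_len)
    return "".join(rng.choice(_VALUE_ALPHABET) for _ in range(n))


def random_eutils_request(rng: random.Random) -> EutilsRequest:
    function = rng.choice(["esearch", "efetch", "esummary"])
    db = rng.choice(["gene", "snp", "omim", "nt", "protein"])
    params = {}
    if function == "esearch":
        params["term"] = random_value(rng)
    else:
        params["id"] = ",".join(str(rng.randint(1, 10**6)) for _ in range(rng.randint(1, 3)))
    for key in ("retmax", "retmode", "sort"):
        if rng.random() < 0.5:
            params[key] = random_value(rng, 1, 8)
    return EutilsRequest(function, db, params)


def random_blast_request(rng: random.Random) -> BlastRequest:
    if rng.random() < 0.5:
        seq = "".join(rng.choice("ACGTN") for _ in range(rng.randint(10, 80)))
        return BlastRequest("Put", program="blastn", database="nt", query=seq)
    return BlastRequest("Get", rid=random_value(rng, 5, 12).replace(" ", "X"))
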