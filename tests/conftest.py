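import pytest

from skiff import (
    CohortConfig,
    InProcessTransport,
    MockDicomWeb,
    MockFhirServer,
    ResourceStore,
    ServerConfig,
    create_session,
    generate_cohort,
)


def make_session(server, **config_kwargs):
    """A no-auth session routed to an in-process mock server."""
    config = ServerConfig(base_url=server.base_url, **config_kwargs)
    return create_session(config, transport=InProcessTransport(server))


@pytest.fixture(scope="session")
def store():
    """A read-only mid-sized synthetic store shared across tests."""
    built = generate_cohort(CohortConfig(n_patients=20, seed=3))
    built.check_integrity()
    return built


@pytest.fixture
def server(store):
    return MockFhirServer(store)


@pytest.fixture
def session(server):
    return make_session(server)


@pytest.fixture
def dicom_server(store):
    return MockDicomWeb(store)


def tiny_patient_store(n: int = 5) -> ResourceStore:
    store = ResourceStore()
    for i in range(n):
        store.add(
            {
                "resourceType": "Patient",
                "id": f"p{i}",
                "gender": "female" if i % 2 == 0 else "male",
                "birthDate": f"19{50 + i}-01-01",
            }
        )
    return store
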