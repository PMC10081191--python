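format-version: 1.2
ontology: go-mock

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process
alt_id: GO:7654321

[Term]
id: GO:1000001
name: mock process 0001
namespace: biological_process
is_a: GO:0008152 ! parent

[Term]
id: GO:1000002
name: mock process 0002
namespace: biological_process
is_a: GO:0008152 ! parent

[Term]
id: GO:1000003
name: mock process 0003
namespace: biological_process
is_a: GO:1000002 ! parent

[Term]
id: GO:1000004
name: mock process 0004
namespace: biological_process
is_a: GO:1000002 ! parent

[Term]
id: GO:1000005
name: mock process 0005
namespace: biological_process
is_a: GO:0008152 ! parent
is_a: GO:1000001 ! parent

[Term]
id: GO:1000006
name: mock process 0006
namespace: biological_process
is_a: GO:0008152 ! parent

[Term]
id: GO:1000007
name: mock process 0007
namespace: biological_process
is_a: GO:1000003 ! parent

[Term]
id: GO:0099999
name: unrelated signaling
namespace: biological_process

[Term]
id: GO:0098765
name: outdated process
namespace: biological_process
is_a: GO:0008152
is_obsolete: true

[Typedef]
id: part_of
name: part of
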