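{"bco_type":"general","description":{"keywords":["toy","validation"],"platform":"local","steps":[{"description":"filter raw reads","inputs":[{"uri":"file://data/raw.fastq"}],"name":"filter","number":1,"outputs":[{"uri":"file://work/filtered.fastq"}],"version":"0.1.0"},{"description":"call variants","inputs":[{"uri":"file://work/filtered.fastq"}],"name":"call","number":2,"outputs":[{"uri":"file://work/calls.vcf"}],"version":"0.2.0"}],"xrefs":[{"ids":["562"],"namespace":"taxonomy"}]},"execution":{"environment_variables":[{"key":"THREADS","value":"1"}],"external_data_endpoints":[{"name":"reference","uri":"https://example.org/ref"}],"script_driver":"shell","scripts":["https://example.org/pipelines/toy.sh"],"software_prerequisites":[{"name":"toycaller","uri":"https://example.org/toycaller","version":"0.2.0"}]},"io":{"inputs":[{"filename":"raw.fastq","uri":"file://data/raw.fastq"}],"outputs":[{"filename":"calls.vcf","uri":"file://work/calls.vcf"}]},"object_id":"https://example.org/bco/minimal-0001","parametric":{"parameters":[{"param":"min_qual","step":2,"value":"30"}]},"provenance":{"contributors":[{"affiliation":"Example Institute","contribution":["authoredBy","curatedBy"],"email":"ada@example.org","name":"Ada Example","orcid":"https://orcid.org/0000-0002-1825-0097"}],"created":"2024-01-15T12:00:00Z","inheritance":[],"license":"CC-BY-4.0","modified":"2024-01-16T09:30:00Z","name":"Minimal toy pipeline","status":"PUBLISHED","version":"1.0.0"},"spec_version":"https://w3id.org/biocompute/1.3.0","usability":{"statements":["Toy two-step pipeline used to exercise BCO validation."]}}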