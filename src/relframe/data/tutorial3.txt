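# complex mixed network: derives two isolated networks
gkuj
h<i
i<k
k<j
l<o
mkuk
n=o
p>o
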