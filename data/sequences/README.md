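# Initiator protein sequences

The sequence-feature checks on the real *D. melanogaster* replication
initiation factors need their full-length protein sequences, which are
not redistributed with this repository. To run them, download the four
sequences (one small FASTA fetch, e.g. from UniProt or FlyBase) and save
them here as FASTA with record ids exactly:

- `Orc1` — Origin recognition complex subunit 1
- `Orc2` — Origin recognition complex subunit 2
- `Cdc6` — Cell division cycle 6
- `Cdt1` — Cdt1 / double parked (dup)

One file per protein or a single multi-record file both work (any
`*.fa` / `*.fasta` name). Example:

```sh
curl -s "https://rest.uniprot.org/uniprotkb/<accession>.fasta" > orc1.fasta
# then edit the header line to read ">Orc1"
```

Note the isoform caveat: the analyzed regions (Orc1 187–548, Orc2 1–269,
Cdt1 1–297) assume the canonical full-length isoforms; a different
isoform shifts the coordinates and the derived pI / motif counts.
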