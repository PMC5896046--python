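<?xml version='1.0' encoding='UTF-8'?>
<entrySet xmlns="http://psi.hupo.org/mi/mif300" level="3" version="0" minorVersion="0">
  <entry>
    <source>
      <names>
        <shortLabel>psimif</shortLabel>
        <fullName>psimif fixture generator</fullName>
      </names>
    </source>
    <experimentList>
      <experimentDescription id="1">
        <names>
          <shortLabel>dependency assay</shortLabel>
        </names>
        <bibref>
          <xref>
            <primaryRef db="pubmed" id="9100004" refType="primary-reference"/>
          </xref>
        </bibref>
        <hostOrganismList>
          <hostOrganism ncbiTaxId="9606">
            <names>
              <shortLabel>human</shortLabel>
            </names>
          </hostOrganism>
        </hostOrganismList>
        <interactionDetectionMethod>
          <names>
            <shortLabel>pull down</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0096" refType="identity"/>
          </xref>
        </interactionDetectionMethod>
        <participantIdentificationMethod>
          <names>
            <shortLabel>predetermined participant</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0396" refType="identity"/>
          </xref>
        </participantIdentificationMethod>
      </experimentDescription>
    </experimentList>
    <interactorList>
      <interactor id="2">
        <names>
          <shortLabel>rcp5</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0004" refType="identity"/>
        </xref>
        <interactorType>
          <names>
            <shortLabel>protein</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0326" refType="identity"/>
          </xref>
        </interactorType>
        <organism ncbiTaxId="9606">
          <names>
            <shortLabel>human</shortLabel>
          </names>
        </organism>
      </interactor>
      <interactor id="3">
        <names>
          <shortLabel>adp3</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0006" refType="identity"/>
        </xref>
        <interactorType>
          <names>
            <shortLabel>protein</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0326" refType="identity"/>
          </xref>
        </interactorType>
        <organism ncbiTaxId="9606">
          <names>
            <shortLabel>human</shortLabel>
          </names>
        </organism>
      </interactor>
    </interactorList>
    <interactionList>
      <interaction id="4">
        <experimentList>
          <experimentRef>1</experimentRef>
        </experimentList>
        <participantList>
          <participant id="5">
            <interactorRef>2</interactorRef>
            <biologicalRole>
              <names>
                <shortLabel>unspecified role</shortLabel>
              </names>
              <xref>
                <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
              </xref>
            </biologicalRole>
            <experimentalRoleList>
              <experimentalRole>
                <names>
                  <shortLabel>bait</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0496" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
            <featureList>
              <feature id="6">
                <names>
                  <shortLabel>required phosphosite</shortLabel>
                </names>
                <featureType>
                  <names>
                    <shortLabel>phosphorylated residue</shortLabel>
                  </names>
                </featureType>
                <featureRole>
                  <names>
                    <shortLabel>prerequisite-ptm</shortLabel>
                  </names>
                  <xref>
                    <primaryRef db="psi-mi" id="MI:0638" refType="identity"/>
                  </xref>
                </featureRole>
                <featureRangeList>
                  <featureRange>
                    <startStatus>
                      <names>
                        <shortLabel>certain</shortLabel>
                      </names>
                      <xref>
                        <primaryRef db="psi-mi" id="MI:0335" refType="identity"/>
                      </xref>
                    </startStatus>
                    <begin position="42"/>
                    <endStatus>
                      <names>
                        <shortLabel>certain</shortLabel>
                      </names>
                      <xref>
                        <primaryRef db="psi-mi" id="MI:0335" refType="identity"/>
                      </xref>
                    </endStatus>
                    <end position="42"/>
                  </featureRange>
                </featureRangeList>
              </feature>
            </featureList>
          </participant>
          <participant id="7">
            <interactorRef>3</interactorRef>
            <biologicalRole>
              <names>
                <shortLabel>unspecified role</shortLabel>
              </names>
              <xref>
                <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
              </xref>
            </biologicalRole>
            <experimentalRoleList>
              <experimentalRole>
                <names>
                  <shortLabel>prey</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0498" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
          </participant>
        </participantList>
        <interactionType>
          <names>
            <shortLabel>physical association</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0915" refType="identity"/>
          </xref>
        </interactionType>
      </interaction>
    </interactionList>
  </entry>
</entrySet>
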