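<?xml version='1.0' encoding='UTF-8'?>
<entrySet xmlns="http://psi.hupo.org/mi/mif300" level="3" version="0" minorVersion="0">
  <entry>
    <source>
      <names>
        <shortLabel>psimif</shortLabel>
        <fullName>psimif fixture generator</fullName>
      </names>
    </source>
    <interactorList>
      <interactor id="1">
        <names>
          <shortLabel>rec1</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0012" refType="identity"/>
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
      <interactor id="2">
        <names>
          <shortLabel>lig3</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0014" refType="identity"/>
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
          <shortLabel>eff2</shortLabel>
        </names>
        <xref>
          <primaryRef db="demo" id="prot-0013" refType="identity"/>
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
      <abstractInteraction id="4">
        <names>
          <shortLabel>rec1-lig3 binding</shortLabel>
        </names>
        <interactionType>
          <names>
            <shortLabel>direct interaction</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0407" refType="identity"/>
          </xref>
        </interactionType>
        <participantList>
          <participant id="5">
            <interactorRef>1</interactorRef>
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
                  <shortLabel>unspecified role</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
          </participant>
          <participant id="6">
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
                  <shortLabel>unspecified role</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
          </participant>
        </participantList>
      </abstractInteraction>
      <abstractInteraction id="7">
        <names>
          <shortLabel>rec1-eff2 complex</shortLabel>
        </names>
        <interactorType>
          <names>
            <shortLabel>complex</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0314" refType="identity"/>
          </xref>
        </interactorType>
        <interactionType>
          <names>
            <shortLabel>physical association</shortLabel>
          </names>
          <xref>
            <primaryRef db="psi-mi" id="MI:0915" refType="identity"/>
          </xref>
        </interactionType>
        <participantList>
          <participant id="8">
            <interactorRef>1</interactorRef>
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
                  <shortLabel>unspecified role</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
          </participant>
          <participant id="9">
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
                  <shortLabel>unspecified role</shortLabel>
                </names>
                <xref>
                  <primaryRef db="psi-mi" id="MI:0499" refType="identity"/>
                </xref>
              </experimentalRole>
            </experimentalRoleList>
          </participant>
        </participantList>
        <cooperativeEffectList>
          <allostery>
            <cooperativityEvidenceList>
              <cooperativityEvidenceDescription>
                <bibref>
                  <xref>
                    <primaryRef db="pubmed" id="9100007" refType="primary-reference"/>
                  </xref>
                </bibref>
                <evidenceMethodList>
                  <evidenceMethod>
                    <names>
                      <shortLabel>inferred by author</shortLabel>
                    </names>
                    <xref>
                      <primaryRef db="psi-mi" id="MI:0363" refType="identity"/>
                    </xref>
                  </evidenceMethod>
                </evidenceMethodList>
              </cooperativityEvidenceDescription>
            </cooperativityEvidenceList>
            <affectedInteractionList>
              <affectedInteractionRef>4</affectedInteractionRef>
            </affectedInteractionList>
            <cooperativeEffectOutcome>
              <names>
                <shortLabel>positive cooperative effect</shortLabel>
              </names>
              <xref>
                <primaryRef db="psi-mi" id="MI:1154" refType="identity"/>
              </xref>
            </cooperativeEffectOutcome>
            <allostericMoleculeRef>8</allostericMoleculeRef>
            <allostericEffectorRef>9</allostericEffectorRef>
          </allostery>
        </cooperativeEffectList>
      </abstractInteraction>
    </interactionList>
  </entry>
</entrySet>
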